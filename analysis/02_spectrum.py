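"""Substitution spectrum, mutation density, zygosity and uniqueness.

Reads the population written by 01_simulate.py, applies the hard filters
(no-ops here since the simulator emits no filter annotations), and tallies
the per-line and pooled spectra. Expected outcome: the pooled G/C>A/T
frequency sits near the generating 27.86% scaled by the site-pool tilt,
homozygous calls near 16.7%, and within-pair sharing halves uniqueness.

Writes results/spectrum_summary.json and results/spectrum_per_line.tsv.
"""

import glob
import json
from pathlib import Path

from emsmut.spectrum_stats import (
    mutation_density,
    per_contig_counts,
    percent_unique_vs_panel,
    spectrum_table,
    unique_snps,
    zygosity_fractions,
)
from emsmut.variant_io import apply_hard_filters, read_vcf

ROOT = Path(__file__).resolve().parent.parent
SIM_DIR = ROOT / "scratch" / "analysis_sim"


def main() -> None:
    line_paths = sorted(glob.glob(str(SIM_DIR / "line*.vcf")))
    if not line_paths:
        raise SystemExit("run analysis/01_simulate.py first")
    population = [apply_hard_filters(read_vcf(p)) for p in line_paths]
    panel = [read_vcf(p) for p in sorted(glob.glob(str(SIM_DIR / "panel*.vcf")))]
    genome_bp = sum(
        json.load(open(SIM_DIR / "truth.json"))["contig_lengths"].values()
    )

    rows = []
    for vs in population:
        spec = spectrum_table(vs)
        dens = mutation_density(spec.n_total, genome_bp)
        zyg = zygosity_fractions(vs.snps())
        novel = percent_unique_vs_panel(vs, panel)
        rows.append({
            "line": vs.line_id, "n_snps": spec.n_total,
            "gc_at": spec.frequencies["GC>AT"], "at_gc": spec.frequencies["AT>GC"],
            "kb_per_mutation": dens.kb_per_mutation, "hom_percent": zyg["hom"],
            "novel_vs_panel_percent": novel,
        })
    pooled = spectrum_table(v for vs in population for v in vs)
    uniq = unique_snps(population)

    out = {
        "pooled_spectrum_percent": pooled.frequencies,
        "pooled_per_contig": per_contig_counts(v for vs in population for v in vs),
        "mean_hom_percent": sum(r["hom_percent"] for r in rows) / len(rows),
        "mean_kb_per_mutation": sum(r["kb_per_mutation"] for r in rows) / len(rows),
        "mean_novel_vs_panel_percent": sum(r["novel_vs_panel_percent"] for r in rows) / len(rows),
        "population_unique_total": uniq.population_unique_total,
        "per_line_unique_percent": uniq.per_line_percent,
    }
    (ROOT / "results").mkdir(exist_ok=True)
    with open(ROOT / "results" / "spectrum_summary.json", "w") as fh:
        json.dump(out, fh, indent=1)
    with open(ROOT / "results" / "spectrum_per_line.tsv", "w") as fh:
        fh.write("line\tn_snps\tGC>AT\tAT>GC\tkb_per_mutation\thom_percent\tnovel_percent\n")
        for r in rows:
            fh.write(f"{r['line']}\t{r['n_snps']}\t{r['gc_at']:.2f}\t{r['at_gc']:.2f}\t"
                     f"{r['kb_per_mutation']:.3f}\t{r['hom_percent']:.2f}\t"
                     f"{r['novel_vs_panel_percent']:.2f}\n")
    print(f"pooled GC>AT {pooled.frequencies['GC>AT']:.2f}%  "
          f"AT>GC {pooled.frequencies['AT>GC']:.2f}%  "
          f"mean hom {out['mean_hom_percent']:.2f}%  "
          f"mean density {out['mean_kb_per_mutation']:.3f} kb/mutation")
    print(f"unique SNPs in population: {uniq.population_unique_total}; "
          f"mean novel vs panel {out['mean_novel_vs_panel_percent']:.2f}%")


if __name__ == "__main__":
    main()
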