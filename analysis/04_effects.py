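"""Region annotation and coding-effect classification of the population.

Assigns every variant a single region (CDS > UTR > intron > promoter >
intergenic), classifies CDS SNP effects through the transcript-strand
codon, classifies InDel frame consequences, and reports gene-level
fractions. The synthetic genome is mostly intergenic, so the region split
is dominated by intergenic calls, with effects inside CDS near the random
expectation (roughly one-quarter synonymous).

Writes results/effects_summary.json.
"""

import glob
import json
from pathlib import Path

from emsmut.coding_effects import effect_summary
from emsmut.reference_io import read_fasta, read_gff3
from emsmut.variant_io import read_vcf

ROOT = Path(__file__).resolve().parent.parent
SIM_DIR = ROOT / "scratch" / "analysis_sim"


def main() -> None:
    line_paths = sorted(glob.glob(str(SIM_DIR / "line*.vcf")))
    if not line_paths:
        raise SystemExit("run analysis/01_simulate.py first")
    genome = read_fasta(SIM_DIR / "genome.fa")
    genes = read_gff3(SIM_DIR / "genes.gff3", genome, promoter_size=1000)
    population = [read_vcf(p) for p in line_paths]
    summary = effect_summary(population, genes, genome)

    indel_totals: dict[str, int] = {}
    for counts in summary.per_line_indels.values():
        for k, n in counts.items():
            indel_totals[k] = indel_totals.get(k, 0) + n

    out = {
        "region_percent": summary.pooled_region_percent,
        "effect_percent": summary.pooled_effect_percent,
        "effect_counts": summary.pooled_effects,
        "gene_fractions_percent": summary.gene_fractions,
        "indel_totals": indel_totals,
    }
    (ROOT / "results").mkdir(exist_ok=True)
    with open(ROOT / "results" / "effects_summary.json", "w") as fh:
        json.dump(out, fh, indent=1)
    reg = summary.pooled_region_percent
    print("regions: " + "  ".join(f"{r} {p:.2f}%" for r, p in sorted(reg.items(), key=lambda x: -x[1])))
    eff = summary.pooled_effect_percent
    print("CDS effects: " + "  ".join(f"{e} {p:.1f}%" for e, p in eff.items() if p))
    print("gene fractions:", {k: round(v, 1) for k, v in summary.gene_fractions.items()})


if __name__ == "__main__":
    main()
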