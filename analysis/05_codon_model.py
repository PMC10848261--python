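"""Genetic-code neighborhood model and codon mutagenicity.

Computes the theoretical amino-acid substitution matrix under random
mutation, compares the population's observed CDS changes against it
(transition vs transversion average ratios), counts the accessible
change types, and derives per-codon mutagenicity ratios against a
synthetic codon-usage table biased like a real one. Because the simulated
mutations are transition-dominated, the mean transition-type ratio should
exceed the mean transversion-type ratio by severalfold.

Writes results/codon_model.json and results/mutagenicity.tsv.
"""

import glob
import json
from pathlib import Path

import numpy as np

from emsmut.coding_effects import GeneIndex, annotate_region, coding_effect
from emsmut.codon_model import (
    SENSE_CODONS,
    count_change_types,
    mutagenicity_ratios,
    normalize_rows_missense,
    observed_aa_matrix,
    observed_vs_theoretical,
    theoretical_aa_matrix,
)
from emsmut.reference_io import build_usage_table, read_fasta, read_gff3
from emsmut.variant_io import read_vcf

ROOT = Path(__file__).resolve().parent.parent
SIM_DIR = ROOT / "scratch" / "analysis_sim"


def synthetic_usage_table(seed: int = 7):
    """Skewed usage weights standing in for a real organism's table
    (synthetic; no measured codon-usage data enters this analysis)."""
    rng = np.random.default_rng(seed)
    return build_usage_table({c: float(rng.gamma(2.0, 10.0)) for c in sorted(SENSE_CODONS)})


def main() -> None:
    line_paths = sorted(glob.glob(str(SIM_DIR / "line*.vcf")))
    if not line_paths:
        raise SystemExit("run analysis/01_simulate.py first")
    genome = read_fasta(SIM_DIR / "genome.fa")
    genes = read_gff3(SIM_DIR / "genes.gff3", genome, promoter_size=1000)
    index = GeneIndex(genes)

    effects = []
    codon_counts: dict[str, int] = {}
    for p in line_paths:
        for v in read_vcf(p).snps():
            ann = annotate_region(v, index)
            if ann.region != "CDS":
                continue
            eff = coding_effect(v, index.genes[ann.gene_id], genome)
            if eff.from_aa != "*":
                effects.append(eff)
                codon_counts[eff.from_codon] = codon_counts.get(eff.from_codon, 0) + 1

    theoretical = theoretical_aa_matrix()
    observed = observed_aa_matrix(effects)
    ratios = observed_vs_theoretical(normalize_rows_missense(observed), theoretical)
    usage = synthetic_usage_table()
    mut = mutagenicity_ratios(codon_counts, usage)

    out = {
        "n_cds_changes": len(effects),
        "theoretical_val_to_ala_percent": theoretical.get("V", "A"),
        "accessible_change_types": count_change_types(),
        "mean_transition_ratio": ratios.mean_transition,
        "mean_transversion_ratio": ratios.mean_transversion,
        "transition_fold_over_transversion": ratios.transition_fold_over_transversion,
    }
    (ROOT / "results").mkdir(exist_ok=True)
    with open(ROOT / "results" / "codon_model.json", "w") as fh:
        json.dump(out, fh, indent=1)
    with open(ROOT / "results" / "mutagenicity.tsv", "w") as fh:
        fh.write("codon\taa\tusage\tobserved\tratio\tpreferred\n")
        for row in mut.rows:
            obs = "" if row["observed"] is None else f"{row['observed']:.4f}"
            rat = "" if row["ratio"] is None else f"{row['ratio']:.4f}"
            fh.write(f"{row['codon']}\t{row['aa']}\t{row['usage']:.4f}\t{obs}\t{rat}\t"
                     f"{int(row['preferred'])}\n")
    print(f"{len(effects)} CDS amino-acid changes; "
          f"mean transition-type ratio {ratios.mean_transition:.2f} vs "
          f"transversion-type {ratios.mean_transversion:.2f} "
          f"({ratios.transition_fold_over_transversion:.2f}-fold)")
    print(f"theoretical Val->Ala {theoretical.get('V', 'A'):.2f}%; "
          f"accessible change types {count_change_types()}")


if __name__ == "__main__":
    main()
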