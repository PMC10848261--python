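"""Generate the synthetic EMS population used by the downstream analyses.

Study conditions: 1 mutation per 3057 bp scaled onto a 2 Mb toy genome,
transition-dominated class probabilities (G/C>A/T 27.86%, A/T>G/C 27.62%),
mutated sites G/C with probability 0.47 on a 37%-GC background, 16.7%
homozygous calls, 6 lines with half the mutations shared within pairs,
InDels, and a 3-set background cultivar panel. Density is raised to
1/500 bp so the toy genome still yields enough CDS hits for the codon
analyses; everything else is at the reported population values.

Writes FASTA/GFF3/VCF/truth under scratch/analysis_sim/ (regenerable) and
a one-line provenance note under results/.
"""

import json
from pathlib import Path

from emsmut.synthetic_data import (
    SimulationConfig,
    record_panel_overlap,
    simulate_background_panel,
    simulate_genome,
    simulate_population,
    write_simulation,
)

ROOT = Path(__file__).resolve().parent.parent
SIM_DIR = ROOT / "scratch" / "analysis_sim"
SEED = 7

CONFIG = SimulationConfig(
    seed=SEED,
    genome_length=2_000_000,
    n_contigs=3,
    n_genes=60,
    n_lines=6,
    density=500.0,
    gc_content=0.37,
    site_gc_prob=0.47,
    hom_fraction=0.167,
    shared_fraction=0.5,
    indels_per_line=120.0,
    promoter_size=1000,
    panel_size=3,
    panel_density=400.0,
)


def main() -> None:
    genome, genes, truth = simulate_genome(CONFIG)
    population, truth = simulate_population(CONFIG, genome, genes, truth)
    panel = simulate_background_panel(CONFIG, genome)
    record_panel_overlap(truth, population, panel)
    paths = write_simulation(SIM_DIR, genome, genes, population, truth, panel)
    n = [len(vs) for vs in population]
    print(f"simulated {len(population)} lines on {genome.total_length / 1e6:.1f} Mb "
          f"({len(genes)} genes); variants per line: {n}")
    print(f"wrote {len(paths)} files to {SIM_DIR}")
    (ROOT / "results").mkdir(exist_ok=True)
    with open(ROOT / "results" / "simulation_config.json", "w") as fh:
        json.dump({"seed": SEED, "sim_dir": str(SIM_DIR),
                   "n_lines": CONFIG.n_lines, "genome_length": CONFIG.genome_length,
                   "density_bp_per_mutation": CONFIG.density}, fh, indent=1)


if __name__ == "__main__":
    main()
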