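import pytest

from emsmut.synthetic_data import (
    SimulationConfig,
    simulate_genome,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_sim():
    """A compact simulated population reused by read-only tests."""
    cfg = SimulationConfig(
        seed=11,
        genome_length=300_000,
        n_genes=12,
        n_lines=3,
        density=250.0,
        promoter_size=500,
        indels_per_line=15,
    )
    genome, genes, truth = simulate_genome(cfg)
    population, truth = simulate_population(cfg, genome, genes, truth)
    return cfg, genome, genes, population, truth


@pytest.fixture(scope="session")
def sim_dir(small_sim, tmp_path_factory):
    """The small simulation written to disk (FASTA/GFF3/VCF/truth)."""
    from emsmut.synthetic_data import write_simulation

    cfg, genome, genes, population, truth = small_sim
    outdir = tmp_path_factory.mktemp("sim")
    write_simulation(outdir, genome, genes, population, truth)
    return outdir
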