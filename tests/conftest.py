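import pytest

from genefam.pipeline import run_family_analysis
from genefam.synthio import SimConfig, simulate_genome


@pytest.fixture(scope="session")
def sim_genome():
    """One full-size simulated genome with planted duplications."""
    return simulate_genome(SimConfig(seed=11))


@pytest.fixture(scope="session")
def pipeline_result(sim_genome):
    """The full analysis run on the session genome."""
    return run_family_analysis(
        sim_genome.annotation,
        sim_genome.proteins,
        sim_genome.cds,
        sim_genome.seed_alignment,
    )


@pytest.fixture(scope="session")
def small_config():
    """A reduced plan for tests that re-simulate repeatedly."""
    return SimConfig(
        n_chromosomes=3,
        genes_per_chromosome=100,
        n_family_genes=16,
        wgd_blocks=1,
        tandem_pairs=2,
        proximal_pairs=1,
        dispersed_pairs=1,
        seed=0,
    )
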