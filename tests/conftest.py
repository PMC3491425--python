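import pytest

from oxymark.report import run_pipeline
from oxymark.synth import SimulationConfig, generate_genome, plant_modifications

ACCEPTANCE_SEED = 11


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run at the default desk scale (200 MAC contigs,
    10 MIC contigs, polyteny 5x, 100k reads/library), shared across tests."""
    return run_pipeline(SimulationConfig(rng_seed=ACCEPTANCE_SEED))


@pytest.fixture(scope="session")
def small_world():
    """A small genome + 46 h modification track for unit tests."""
    config = SimulationConfig(
        n_mac_chromosomes=20,
        n_cohort_chromosomes=3,
        n_hmc_only_chromosomes=1,
        mic_contigs=[("satellite", 170, 850), ("transposon", 0, 800)],
        n_reads_per_library=20_000,
        rng_seed=5,
    )
    genome = generate_genome(config)
    track = plant_modifications(genome, config)
    return config, genome, track
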