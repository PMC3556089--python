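import pytest
from hypothesis import settings

from dgetag.pipeline import run_pipeline
from dgetag.synthetic_data import SimulationConfig

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_pipeline():
    """Full pipeline on the default simulation (2,000 genes, depth 5e5,
    seed 42); shared across tests because it is the costliest fixture."""
    return run_pipeline(SimulationConfig())


@pytest.fixture(scope="session")
def small_pipeline():
    """A 60-gene pipeline for cheap end-to-end structural checks."""
    config = SimulationConfig(
        n_genes=60,
        n_de_genes=6,
        n_fer_specific_genes=3,
        n_ste_specific_genes=2,
        n_alien_genes=3,
        library_depths=(30_000, 30_000),
        min_expected_count=30.0,
        genes_per_contig=20,
        seed=7,
    )
    return run_pipeline(config)
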