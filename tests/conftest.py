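import numpy as np
import pytest

from gradimmune import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared by read-only tests."""
    cfg = SimulationConfig(
        n_rural=20,
        n_urban=40,
        n_external=30,
        n_species=30,
        n_metabolites=40,
        n_pathways=5,
        n_gradient_species=2,
        immunomod_spec=[("sp_010", 1e-3), ("sp_011", -1e-3)],
        pathway_spec=[("pwy_000", 0.9, -0.6)],
        coupling_spec=[("sp_010", "mz_0000", 0.8)],
    )
    return cfg, simulate_cohort(cfg, seed=42)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
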