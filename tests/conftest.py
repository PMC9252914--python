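import numpy as np
import pytest

from clonevo.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete synthetic cohort shared across tests."""
    cfg = SimulationConfig(
        seed=11,
        n_type1=4,
        n_type2=5,
        depth=100.0,
        atlas_regions=400,
        atlas_samples_per_type=5,
        genome_length=60_000,
    )
    return cfg, simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
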