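import numpy as np
import pytest
from hypothesis import settings

from snoridr import SimulationConfig, gen_reference, gen_sites

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")


@pytest.fixture(scope="session")
def small_config():
    """Noise-free small study: fast enough for per-test simulation."""
    return SimulationConfig(
        seed=7,
        ref_length=400,
        depth=300,
        propensity_sd=0.0,
        n_nm_sites=6,
        n_psi_sites=5,
    )


@pytest.fixture(scope="session")
def small_reference(small_config):
    return gen_reference(small_config)


@pytest.fixture(scope="session")
def small_sites(small_config, small_reference):
    return gen_sites(small_reference, small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
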