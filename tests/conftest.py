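import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_dimer():
    """Small two-chain contact dimer used across the structure tests."""
    from nitroredscope.synth_data import SimConfig, gen_toy_dimer

    return gen_toy_dimer(SimConfig(seed=5), n_atoms_per_chain=25, separation=6.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
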