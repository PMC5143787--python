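import numpy as np
import pytest

from scpkaczmarz import make_scenario, two_target_config


@pytest.fixture(scope="session")
def two_target_noisy():
    """Default two-target scenario (1% noise, default seed)."""
    return make_scenario(two_target_config())


@pytest.fixture(scope="session")
def two_target_noiseless():
    """Same geometry with exact (noise-free) measurements."""
    return make_scenario(two_target_config(noise_level=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
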