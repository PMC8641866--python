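import numpy as np
import pytest

from rfarn.model import NetworkConfig
from rfarn.synthetic import SynthConfig, generate_sample


@pytest.fixture(scope="session")
def synth_sample():
    """One deterministic synthetic fundus sample (128x128)."""
    return generate_sample(SynthConfig(seed=7), 0)


@pytest.fixture(scope="session")
def reduced_net():
    """Narrow network configuration used to keep tests quick."""
    return NetworkConfig(base_channels=8, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
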