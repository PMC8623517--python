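import numpy as np
import pytest

from wfsan.network import NetworkConfig, WFSAN


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def random_image(rng):
    """A random 8-bit 32x32 grayscale image as float64."""
    return rng.integers(0, 256, size=(32, 32)).astype(np.float64)


@pytest.fixture
def tiny_model():
    """Small non-residual network for plain forward/backward tests."""
    return WFSAN(NetworkConfig(scale=2, base_filters=4, residual=False), seed=7)
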