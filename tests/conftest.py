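import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng):
    """Small random RGB uint8 image."""
    return rng.integers(0, 256, size=(12, 12, 3), dtype=np.uint8)


@pytest.fixture
def random_gray(rng):
    return rng.integers(0, 256, size=(12, 12)).astype(np.float64)
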