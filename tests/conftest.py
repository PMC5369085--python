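import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_tone():
    """Sum of a fast and a slow tone, the classic EMD separation case."""
    t = np.arange(1024.0)
    fast = np.sin(2 * np.pi * t / 8)
    slow = np.sin(2 * np.pi * t / 64)
    return fast + slow, fast, slow
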