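import numpy as np
import pytest

from respglm import RespirationTrace


@pytest.fixture
def sine_trace():
    """4 s-period sinusoid at 10 Hz, 300 s, amplitude 2, negative crossing at t=0."""
    t = np.arange(3000) / 10.0
    return RespirationTrace(-2.0 * np.sin(2 * np.pi * t / 4.0), fs=10.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
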