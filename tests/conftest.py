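import numpy as np
import pytest

from assrlab import AudioSignal, EnhancementParams


@pytest.fixture
def params():
    return EnhancementParams()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noise_signal(rng):
    """Two seconds of stationary noise at the enhancement rate."""
    return AudioSignal(0.2 * rng.standard_normal(32000), 16000.0)
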