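import numpy as np
import pytest

from polstim.frame_codec import DisplaySpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def spec():
    """The printed display configuration: 60 Hz, 24-bit, 4-bit depth."""
    return DisplaySpec(width=64, height=64, degrees_per_pixel=0.25)
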