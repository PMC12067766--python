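import numpy as np
import pytest

from rrseg.synthetic import SynthConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A light generator config for fast unit tests (64-px frames)."""
    return SynthConfig(image_size_px=64, n_rods=(2, 4), n_rings=(2, 4), seed=7)
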