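import numpy as np
import pytest

from staz import ChannelImage, LiverMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def square_mask():
    """32x32 grid with a 16x16 liver square in the middle."""
    m = np.zeros((32, 32), dtype=bool)
    m[8:24, 8:24] = True
    return LiverMask(m)


def channel(pixels, role="lipid_green"):
    return ChannelImage(np.asarray(pixels, dtype=float), role)


@pytest.fixture
def make_channel():
    return channel
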