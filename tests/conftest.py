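import numpy as np
import pytest

from cytocluster.imageio_core import BinaryMask, ChannelImage


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def gray64():
    """A 64x64 grayscale image with a dark square on bright background."""
    px = np.full((64, 64), 200, dtype=np.uint8)
    px[20:40, 20:40] = 80
    return ChannelImage(px)


@pytest.fixture
def rgb64():
    px = np.zeros((64, 64, 3), dtype=np.uint8)
    px[:, :, 1] = 150
    return ChannelImage(px)


def disk_mask(height, width, cr, cc, radius):
    rr, cc_ = np.ogrid[:height, :width]
    return BinaryMask((rr - cr) ** 2 + (cc_ - cc) ** 2 <= radius**2)


@pytest.fixture
def disk100():
    """Centered filled disk, radius 20, in a 100x100 frame."""
    return disk_mask(100, 100, 50, 50, 20)
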