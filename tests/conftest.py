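import numpy as np
import pytest

from varpscan import GrayImage


@pytest.fixture
def white_image() -> GrayImage:
    return GrayImage(np.full((600, 800), 255, dtype=np.uint8))


@pytest.fixture
def bars_image() -> GrayImage:
    """White 1000x1000 image with 5 disjoint solid black 8x60 bars.

    Bars are axis-aligned with their long axis vertical, centers on a
    horizontal line: ground truth for rectangle detection tests.
    """
    img = np.full((1000, 1000), 255, dtype=np.uint8)
    for cx in bar_centers():
        img[470:530, cx - 4 : cx + 4] = 0
    return GrayImage(img)


def bar_centers() -> list[int]:
    return [150, 320, 490, 660, 830]


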