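import numpy as np
import pytest

from tjquant.image_io import BinaryMask, GrayImage


@pytest.fixture
def constant_image():
    def make(value: int = 50, size: int = 64, um_per_pixel: float = 1.0) -> GrayImage:
        return GrayImage(np.full((size, size), value, dtype=np.uint8), um_per_pixel=um_per_pixel)

    return make


@pytest.fixture
def two_level_image():
    """Left half `low`, right half `high` — a clean bimodal test image."""

    def make(low: int = 10, high: int = 200, size: int = 64) -> GrayImage:
        px = np.full((size, size), low, dtype=np.uint8)
        px[:, size // 2:] = high
        return GrayImage(px)

    return make


@pytest.fixture
def mask_from():
    def make(bool_array, um_per_pixel: float = 1.0) -> BinaryMask:
        return BinaryMask(np.asarray(bool_array, dtype=bool), um_per_pixel=um_per_pixel)

    return make
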