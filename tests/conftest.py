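import numpy as np
import pytest

from fsafcm import GrayImage, make_two_region

# 3x3 gray patch around an impulse-noise pixel (bright vessel dot on dark
# parenchyma); window sum 613, so the window mean is 613/9.
VESSEL_NOISE_PATCH = np.array(
    [[78.0, 53.0, 53.0], [60.0, 142.0, 52.0], [60.0, 59.0, 56.0]]
)


@pytest.fixture
def vessel_noise_patch():
    return VESSEL_NOISE_PATCH.copy()


@pytest.fixture
def two_region():
    """Noiseless 64x64 image, left half 40 and right half 200, plus truth mask."""
    return make_two_region(64)


@pytest.fixture
def random_image():
    def _make(seed: int, shape=(48, 48), levels: int = 256) -> GrayImage:
        rng = np.random.default_rng(seed)
        return GrayImage(rng.integers(0, levels, shape).astype(float))

    return _make
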