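import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from skimage import draw

from ocmkit import CompressionCycleSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

TONGUE_RGB = (186, 130, 140)
TABLET_RGB = (202, 36, 46)


@pytest.fixture
def cycle_spec() -> CompressionCycleSpec:
    return CompressionCycleSpec()


def make_scene(shape=(200, 200), discs=(), bg=TONGUE_RGB, fg=TABLET_RGB,
               noise_sd=0.0, seed=0):
    """Paint filled discs on a tongue-coloured background.

    ``discs`` is a sequence of (row, col, radius).  Returns (frame,
    drawn_pixel_count); overlapping discs are counted once.
    """
    img = np.empty(shape + (3,), dtype=np.uint8)
    img[:] = bg
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        noisy = img.astype(float) + rng.normal(0, noise_sd, img.shape)
        img = np.clip(noisy, 0, 255).astype(np.uint8)
    painted = np.zeros(shape, dtype=bool)
    for r, c, rad in discs:
        rr, cc = draw.disk((r, c), rad, shape=shape)
        img[rr, cc] = fg
        painted[rr, cc] = True
    return img, int(painted.sum())
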