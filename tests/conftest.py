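import numpy as np
import pytest
from hypothesis import settings

from steatoquant import SlideImage

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")


@pytest.fixture
def flat_slide():
    """Factory for a uniformly coloured RGB slide."""

    def make(color=(255, 255, 255), shape=(10, 10)):
        px = np.empty((*shape, 3), dtype=np.uint8)
        px[:] = color
        return SlideImage(px, source_id="flat")

    return make


@pytest.fixture
def disk_slide():
    """A dark tissue disk on a white background, plus its disk mask."""
    h = w = 64
    yy, xx = np.mgrid[0:h, 0:w]
    disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 20**2
    px = np.full((h, w, 3), 255, dtype=np.uint8)
    px[disk] = (102, 102, 102)
    return SlideImage(px, source_id="disk"), disk


def random_oracle_image(rng: np.random.Generator, max_side: int = 64) -> np.ndarray:
    """A small random test image: noisy mid-gray tissue in a white frame
    with a few bright patches (disk- and bar-shaped)."""
    h = int(rng.integers(24, max_side + 1))
    w = int(rng.integers(24, max_side + 1))
    gray = rng.uniform(0.30, 0.70, size=(h, w))
    for _ in range(int(rng.integers(0, 7))):
        bright = float(rng.uniform(0.85, 1.0))
        if rng.random() < 0.5:
            r0 = int(rng.integers(3, h - 3))
            c0 = int(rng.integers(3, w - 3))
            rad = int(rng.integers(2, 9))
            yy, xx = np.mgrid[0:h, 0:w]
            gray[(yy - r0) ** 2 + (xx - c0) ** 2 <= rad**2] = bright
        else:
            r0 = int(rng.integers(3, h - 4))
            c0 = int(rng.integers(3, max(4, w - 12)))
            gray[r0 : r0 + int(rng.integers(2, 4)), c0 : c0 + int(rng.integers(3, 13))] = bright
    frame = 2  # white border so background exists
    gray[:frame, :] = gray[-frame:, :] = 1.0
    gray[:, :frame] = gray[:, -frame:] = 1.0
    vals = np.round(gray * 255).astype(np.uint8)
    return np.stack([vals] * 3, axis=-1)
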