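import numpy as np
import pytest

from wheatspa.segmentation import GrayImage
from wheatspa.synthetic import ImagingSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def imaging():
    """Default virtual imaging booth (noise-free variant via replace)."""
    return ImagingSpec()


@pytest.fixture
def random_image(rng):
    return GrayImage(rng.integers(0, 256, size=(48, 40)), bit_depth=8)


def brute_force_otsu(histogram):
    """Independent exhaustive-scan oracle for the Otsu threshold.

    Evaluates the between-class variance of every split (background =
    levels < t) with plain Python loops and returns the lowest maximizing
    level.
    """
    hist = list(histogram)
    best_t, best_sigma = None, -1.0
    for t in range(1, len(hist)):
        w0 = sum(hist[:t])
        w1 = sum(hist[t:])
        if w0 == 0 or w1 == 0:
            continue
        mu0 = sum(level * count for level, count in enumerate(hist[:t])) / w0
        mu1 = sum(level * hist[level] for level in range(t, len(hist))) / w1
        sigma = w0 * w1 * (mu0 - mu1) ** 2
        if sigma > best_sigma:
            best_t, best_sigma = t, sigma
    return best_t
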