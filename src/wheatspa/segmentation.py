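"""Silhouette segmentation of fluorescence-style plant images.

A chlorophyll-fluorescence image shows the plant as a bright silhouette on a
dark background, so a single global threshold separates plant from
non-plant.  The pipeline is: Otsu threshold on the gray-level histogram →
binarization (pixels below the threshold are background) → morphological
opening and closing to remove speckle noise and fill pinholes.
"""

from __future__ import annotations

from dataclasses import dataclass

import imageio.v3 as iio
import numpy as np
from skimage.measure import label
from skimage.morphology import closing as _closing
from skimage.morphology import disk
from skimage.morphology import opening as _opening

__all__ = [
    "GrayImage",
    "MorphologyConfig",
    "DegenerateHistogramError",
    "gray_histogram",
    "otsu_threshold",
    "binarize",
    "clean_mask",
    "segment",
    "read_gray_image",
    "write_mask_png",
]


class DegenerateHistogramError(ValueError):
    """All pixels share one gray level: no foreground/background split exists."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale image with explicit bit depth.

    ``pixels`` is a row-major array of non-negative integer intensities,
    origin at the top-left, row index increasing downward.  All intensities
    must be representable at ``bit_depth`` (default 8, i.e. levels 0..255).
    """

    pixels: np.ndarray
    bit_depth: int = 8

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixels must have an integer dtype")
        if px.min() < 0 or px.max() >= 2**self.bit_depth:
            raise ValueError(f"intensities out of range for {self.bit_depth}-bit image")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_levels(self) -> int:
        return 2**self.bit_depth


@dataclass(frozen=True)
class MorphologyConfig:
    """Disk-structuring-element cleanup applied after binarization.

    Opening (radius ``opening_radius``) removes isolated bright speckle;
    closing (radius ``closing_radius``) fills small holes inside the plant.
    A radius of 0 disables the corresponding operation.  ``keep_largest``
    optionally retains only the largest connected component; it is off by
    default because the baseline pipeline relies on morphology alone.
    """

    opening_radius: int = 1
    closing_radius: int = 1
    keep_largest: bool = False

    def __post_init__(self) -> None:
        if self.opening_radius < 0 or self.closing_radius < 0:
            raise ValueError("morphology radii must be non-negative")


DEFAULT_MORPHOLOGY = MorphologyConfig()


def gray_histogram(image: GrayImage) -> np.ndarray:
    """Per-level pixel counts over the image's full ``2**bit_depth`` range."""
    return np.bincount(image.pixels.ravel(), minlength=image.n_levels)


def otsu_threshold(histogram: np.ndarray) -> int:
    """Threshold level maximizing between-class variance.

    The candidate threshold ``t`` splits gray levels into background
    (level < t) and foreground (level >= t), matching :func:`binarize`.
    Returns the level maximizing sigma_B^2(t) = w0*w1*(mu0 - mu1)^2; ties
    are broken by the lowest maximizing level.

    Raises
    ------
    DegenerateHistogramError
        If fewer than two gray levels are populated.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size < 2:
        raise ValueError("histogram must be 1-D with at least two bins")
    if hist.min() < 0:
        raise ValueError("histogram counts must be non-negative")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError("histogram has fewer than two populated levels")

    levels = np.arange(hist.size, dtype=np.float64)
    # Class 0 at threshold t holds levels 0..t-1, class 1 holds t..L-1.
    w0 = np.cumsum(hist)[:-1]                  # weight of class 0 for t = 1..L-1
    m0 = np.cumsum(hist * levels)[:-1]         # unnormalized first moment
    total = hist.sum()
    total_m = float(hist @ levels)
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (total_m - m0) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b[(w0 == 0) | (w1 == 0)] = -np.inf   # only splits with two populated classes
    return int(np.argmax(sigma_b)) + 1         # +1: index i corresponds to t = i+1


def binarize(image: GrayImage, threshold: int) -> np.ndarray:
    """Binary mask: 0 where the pixel value is below ``threshold``, else 1."""
    if not 0 <= threshold < image.n_levels:
        raise ValueError(f"threshold {threshold} outside [0, {image.n_levels})")
    return (image.pixels >= threshold).astype(np.uint8)


def clean_mask(mask: np.ndarray, cfg: MorphologyConfig = DEFAULT_MORPHOLOGY) -> np.ndarray:
    """Morphological opening then closing with disk structuring elements."""
    out = np.asarray(mask).astype(bool)
    if cfg.opening_radius > 0:
        out = _opening(out, disk(cfg.opening_radius))
    if cfg.closing_radius > 0:
        out = _closing(out, disk(cfg.closing_radius))
    if cfg.keep_largest and out.any():
        labels = label(out, connectivity=2)
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        out = labels == np.argmax(counts)
    return out.astype(np.uint8)


def segment(image: GrayImage, cfg: MorphologyConfig = DEFAULT_MORPHOLOGY) -> np.ndarray:
    """Full segmentation: Otsu threshold → binarize → morphological cleanup."""
    threshold = otsu_threshold(gray_histogram(image))
    return clean_mask(binarize(image, threshold), cfg)


def read_gray_image(path, bit_depth: int = 8, channel: int | None = None) -> GrayImage:
    """Read a PNG/TIFF grayscale image from disk.

    Multi-channel inputs are rejected unless ``channel`` selects a plane.
    """
    arr = iio.imread(path)
    if arr.ndim == 3:
        if channel is None:
            raise ValueError(
                f"{path}: multi-channel image; pass channel= to select a plane"
            )
        arr = arr[..., channel]
    elif arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D grayscale image, got shape {arr.shape}")
    return GrayImage(arr.astype(np.int64), bit_depth=bit_depth)


def write_mask_png(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit PNG with foreground = 255."""
    iio.imwrite(path, (np.asarray(mask, dtype=np.uint8) * 255))
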