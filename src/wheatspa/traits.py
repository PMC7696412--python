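"""Geometric traits from binary plant masks.

Side-projected area (SPA) is the sum of foreground pixels in the mask;
height and width are the sides of the axis-aligned rectangle enclosing the
foreground.  Pixel measurements are calibrated to physical units with a
scalar mm-per-pixel factor (lengths scale linearly, areas quadratically),
and the per-plant SPA at a time point is the mean over the rotational
views (nominally 12 at 30° steps).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Calibration",
    "PlantGeometry",
    "AggregatedSPA",
    "EmptyMaskError",
    "side_projected_area",
    "bounding_extent",
    "measure",
    "calibrate",
    "aggregate_angles",
]


class EmptyMaskError(ValueError):
    """A geometric trait was requested on a mask with no foreground pixels."""


@dataclass(frozen=True)
class Calibration:
    """Scalar image calibration: ``scale`` millimetres per pixel."""

    scale: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise ValueError("calibration scale must be finite and positive")


@dataclass(frozen=True)
class PlantGeometry:
    """Per-view plant geometry, in pixels and (once calibrated) millimetres."""

    spa_px: int
    height_px: int
    width_px: int
    angle_deg: float = 0.0
    spa_mm2: float | None = None
    height_mm: float | None = None
    width_mm: float | None = None


@dataclass(frozen=True)
class AggregatedSPA:
    """Mean SPA over the available rotational views of one plant."""

    spa_mm2: float
    n_views: int


def side_projected_area(mask: np.ndarray) -> int:
    """Foreground pixel count of a binary mask (0 for an empty mask)."""
    return int(np.count_nonzero(mask))


def bounding_extent(mask: np.ndarray) -> tuple[int, int]:
    """Inclusive (height_px, width_px) of the rectangle enclosing the foreground.

    Height is the vertical extent (rows), width the horizontal (columns).
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise EmptyMaskError("mask has no foreground pixels")
    return int(rows.max() - rows.min() + 1), int(cols.max() - cols.min() + 1)


def measure(mask: np.ndarray, angle_deg: float = 0.0) -> PlantGeometry:
    """Pixel-space geometry (SPA, height, width) of one mask."""
    height, width = bounding_extent(mask)
    return PlantGeometry(
        spa_px=side_projected_area(mask),
        height_px=height,
        width_px=width,
        angle_deg=angle_deg,
    )


def calibrate(geom: PlantGeometry, cal: Calibration) -> PlantGeometry:
    """Fill physical units: lengths × scale, areas × scale²."""
    return replace(
        geom,
        spa_mm2=geom.spa_px * cal.scale**2,
        height_mm=geom.height_px * cal.scale,
        width_mm=geom.width_px * cal.scale,
    )


def aggregate_angles(views: Sequence[PlantGeometry]) -> AggregatedSPA:
    """Arithmetic-mean SPA over a plant's rotational views.

    Warns (does not fail) when the number of views differs from the nominal
    12, so that series with missing frames still aggregate.
    """
    if len(views) == 0:
        raise ValueError("at least one view is required")
    areas = []
    for v in views:
        if v.spa_mm2 is None:
            raise ValueError("views must be calibrated before aggregation")
        areas.append(v.spa_mm2)
    if len(views) != 12:
        warnings.warn(
            f"aggregating {len(views)} views instead of the nominal 12",
            stacklevel=2,
        )
    return AggregatedSPA(spa_mm2=float(np.mean(areas)), n_views=len(views))
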