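"""Relative growth rates and the compound-interest growth law.

The study's interval relative growth rate (RGR) is the simple ratio

    RGR = (W2 - W1) / (W1 * (t2 - t1)),

the trait increase over an interval relative to its initial value, per day.
Dry-weight RGRs are conventionally reported in mg g^-1 d^-1 (unit scale
1000); area-based RGRs in mm^2 mm^-2 d^-1 (unit scale 1).  The classical
log-difference rate ln(W2/W1)/dt — exact under exponential growth
W(t) = W0 * exp(r*t) — is provided as an explicit alternative, and
:func:`fit_compound_interest` estimates (W0, r) of that exponential law by
least squares on log-transformed values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TraitSeries",
    "IntervalRGR",
    "GrowthFit",
    "interval_rgr",
    "rgr_table",
    "classical_rgr",
    "fit_compound_interest",
]

#: Conventional unit scale per trait: dry weights in mg g^-1 d^-1, areas as bare fractions.
UNIT_SCALES = {"BIO": 1000.0, "LDW": 1000.0, "LA": 1.0, "SPA": 1.0}
RGR_UNITS = {
    "BIO": "mg g-1 d-1",
    "LDW": "mg g-1 d-1",
    "LA": "cm2 cm-2 d-1",
    "SPA": "mm2 mm-2 d-1",
}


@dataclass(frozen=True)
class TraitSeries:
    """Ordered (DAP, value) trajectory of one trait.

    ``level`` records whether values are per-plant measurements or
    per-genotype means (the destructive design only supports means).
    """

    trait: str
    unit: str
    dap: tuple[float, ...]
    values: tuple[float, ...]
    level: str = "genotype-mean"

    def __post_init__(self) -> None:
        if len(self.dap) != len(self.values):
            raise ValueError("dap and values must have equal length")
        if any(b <= a for a, b in zip(self.dap, self.dap[1:])):
            raise ValueError("dap must be strictly increasing")
        if any(v < 0 for v in self.values):
            raise ValueError("trait values must be non-negative")


@dataclass(frozen=True)
class IntervalRGR:
    trait: str
    dap_start: float
    dap_end: float
    value: float
    unit: str


@dataclass(frozen=True)
class GrowthFit:
    """Exponential growth law W(t) = w0 * exp(r * t); r is the efficiency index (d^-1)."""

    w0: float
    r: float

    def predict(self, t) -> np.ndarray:
        return self.w0 * np.exp(self.r * np.asarray(t, dtype=float))


def interval_rgr(
    w1: float,
    w2: float,
    t1: float,
    t2: float,
    unit_scale: float = 1.0,
    trait: str = "",
    unit: str = "",
) -> IntervalRGR:
    """Simple-ratio RGR over one interval: scale * (w2 - w1) / (w1 * (t2 - t1)).

    Negative rates are allowed (the trait shrank); ``w1`` must be positive
    and ``t2`` must exceed ``t1``.
    """
    if w1 <= 0:
        raise ValueError("initial value w1 must be positive (undefined baseline)")
    if t2 <= t1:
        raise ValueError("interval end must exceed interval start")
    value = unit_scale * (w2 - w1) / (w1 * (t2 - t1))
    return IntervalRGR(trait=trait, dap_start=t1, dap_end=t2, value=value, unit=unit)


def rgr_table(series: TraitSeries, unit_scale: float | None = None) -> list[IntervalRGR]:
    """Interval RGRs over consecutive time points: n points → n−1 intervals.

    ``unit_scale`` defaults to the trait's conventional scale (1000 for dry
    weights, 1 for areas).
    """
    if len(series.dap) < 2:
        raise ValueError("at least two time points are required")
    if unit_scale is None:
        unit_scale = UNIT_SCALES.get(series.trait, 1.0)
    unit = RGR_UNITS.get(series.trait, "d-1")
    return [
        interval_rgr(w1, w2, t1, t2, unit_scale, trait=series.trait, unit=unit)
        for (t1, w1), (t2, w2) in zip(
            zip(series.dap, series.values), zip(series.dap[1:], series.values[1:])
        )
    ]


def classical_rgr(w1: float, w2: float, t1: float, t2: float) -> float:
    """Log-difference growth rate ln(w2/w1)/(t2−t1), in fraction per day.

    Agrees with the simple-ratio RGR to first order when the relative
    increase is small, and is the exact rate under exponential growth.
    """
    if w1 <= 0 or w2 <= 0:
        raise ValueError("weights must be positive")
    if t2 <= t1:
        raise ValueError("interval end must exceed interval start")
    return (math.log(w2) - math.log(w1)) / (t2 - t1)


def fit_compound_interest(series: TraitSeries) -> GrowthFit:
    """Least-squares fit of the exponential law to a trait trajectory.

    Regresses ln W on t; W0 = exp(intercept), r = slope.  With exactly two
    points this reduces to r = ln(W1/W0)/dt.  All values must be positive.
    """
    if len(series.dap) < 2:
        raise ValueError("at least two time points are required")
    values = np.asarray(series.values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("exponential fit requires positive values")
    t = np.asarray(series.dap, dtype=float)
    slope, intercept = np.polyfit(t, np.log(values), 1)
    return GrowthFit(w0=float(np.exp(intercept)), r=float(slope))
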