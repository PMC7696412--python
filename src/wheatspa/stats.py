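"""Validation statistics for the image-based growth surrogates.

How well does the image-derived side-projected area (SPA) stand in for the
destructively measured traits?  The checks are: simple OLS regression with
SPA as the predictor (slope, intercept, R², Pearson r), Pearson correlation
between RGR series, balanced two-way ANOVA (time point × genotype with
interaction), and a log-linear exponential predictor y ≈ a·e^{bx} for the
post-heading regime where the linear SPA→biomass fit breaks down.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

__all__ = [
    "RegressionResult",
    "AnovaTable",
    "ExponentialPredictor",
    "UnbalancedDesignError",
    "ols_simple",
    "pearson",
    "two_way_anova",
    "fit_exponential_predictor",
]


class UnbalancedDesignError(ValueError):
    """The factorial layout has empty or unequal cells; only balanced designs are supported."""


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression summary; ``r2`` is a fraction in [0, 1]."""

    slope: float
    intercept: float
    r2: float
    pearson_r: float
    n: int
    p_value: float

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class AnovaTable:
    """Two-way ANOVA decomposition (type-I SS on a balanced design)."""

    table: pd.DataFrame  # rows: time point, genotype, interaction, residual
    r2: float


@dataclass(frozen=True)
class ExponentialPredictor:
    """Exponential response model y = a * exp(b * x), fitted log-linearly.

    ``r2_log`` is the R² of the regression of ln y on x; ``r2_original`` is
    the pseudo-R² (1 − SS_res/SS_tot) of the back-transformed predictions
    on the original scale.
    """

    a: float
    b: float
    r2_log: float
    r2_original: float

    def predict(self, x) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(x, dtype=float))


def _as_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    return x, y


def ols_simple(x, y) -> RegressionResult:
    """OLS of y on x with a single predictor.

    R² = 1 − SS_res/SS_tot, which equals the squared Pearson correlation for
    a simple regression; the reported Pearson r carries the slope's sign.
    """
    x, y = _as_xy(x, y)
    if x.size < 3:
        raise ValueError("at least three observations are required")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant (degenerate regression)")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        pearson_r=float(fit.rvalue),
        n=int(x.size),
        p_value=float(fit.pvalue),
    )


def pearson(x, y) -> float:
    """Product-moment correlation coefficient."""
    x, y = _as_xy(x, y)
    if x.size < 3:
        raise ValueError("at least three observations are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has undefined correlation")
    return float(sps.pearsonr(x, y).statistic)


def two_way_anova(
    records: pd.DataFrame,
    value: str = "value",
    genotype: str = "genotype",
    time: str = "dap",
) -> AnovaTable:
    """Balanced two-way ANOVA with interaction: value ~ time * genotype.

    Uses a type-I sum-of-squares decomposition, which is order-invariant on
    the balanced layouts this study design produces; unbalanced layouts are
    rejected rather than silently approximated.  The model R² is
    (SS_time + SS_genotype + SS_interaction) / SS_total.
    """
    df = records[[genotype, time, value]].dropna()
    for col in (genotype, time):
        if df[col].nunique() < 2:
            raise ValueError(f"factor {col!r} needs at least two levels")
    cell_sizes = df.groupby([genotype, time], observed=True).size()
    n_cells = df[genotype].nunique() * df[time].nunique()
    if len(cell_sizes) < n_cells or cell_sizes.nunique() != 1:
        raise UnbalancedDesignError("empty or unequal cells; balanced design required")

    data = df.rename(columns={value: "y", genotype: "geno", time: "tp"})
    fit = ols("y ~ C(tp) * C(geno)", data=data).fit()
    raw = anova_lm(fit, typ=1)

    y = data["y"].to_numpy(dtype=float)
    ss_total = float(raw["sum_sq"].sum())
    if float(np.sum((y - y.mean()) ** 2)) <= 1e-12 * max(1.0, y.mean() ** 2) * y.size:
        warnings.warn("all values identical; ANOVA R² reported as 0", stacklevel=2)
        r2 = 0.0
    else:
        r2 = float(raw["sum_sq"][:-1].sum() / ss_total)

    table = raw.rename(
        index={
            "C(tp)": "time point",
            "C(geno)": "genotype",
            "C(tp):C(geno)": "interaction",
            "Residual": "residual",
        }
    ).rename(columns={"sum_sq": "sum_sq", "df": "df", "F": "F", "PR(>F)": "p"})
    table["mean_sq"] = table["sum_sq"] / table["df"]
    table = table[["df", "sum_sq", "mean_sq", "F", "p"]]
    return AnovaTable(table=table, r2=r2)


def fit_exponential_predictor(x, y) -> ExponentialPredictor:
    """Fit y = a·e^{bx} by regressing ln y on x (closed-form, deterministic)."""
    x, y = _as_xy(x, y)
    if x.size < 2:
        raise ValueError("at least two observations are required")
    if np.any(y <= 0):
        raise ValueError("exponential predictor requires positive responses")
    logy = np.log(y)
    b, loga = np.polyfit(x, logy, 1)
    pred_log = loga + b * x
    ss_log = float(np.sum((logy - logy.mean()) ** 2))
    r2_log = 1.0 if ss_log == 0 else 1.0 - float(np.sum((logy - pred_log) ** 2)) / ss_log
    pred = np.exp(pred_log)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_orig = 1.0 if ss_tot == 0 else 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot
    return ExponentialPredictor(
        a=float(np.exp(loga)), b=float(b), r2_log=r2_log, r2_original=r2_orig
    )
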