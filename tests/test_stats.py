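"""Regression, correlation, two-way ANOVA and the exponential predictor."""

import numpy as np
import pandas as pd
import pytest

from wheatspa import reference_data as ref
from wheatspa.stats import (
    UnbalancedDesignError,
    fit_exponential_predictor,
    ols_simple,
    pearson,
    two_way_anova,
)
from wheatspa.utils import round_half_up


def normal_equations_fit(x, y):
    """Independent closed-form OLS oracle from the explicit sums."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def cell_means_anova_ss(df):
    """Direct-summation oracle for balanced two-way ANOVA sums of squares."""
    grand = df["value"].mean()
    n = len(df)
    cells = df.groupby(["genotype", "dap"])["value"]
    a_means = df.groupby("dap")["value"].mean()
    b_means = df.groupby("genotype")["value"].mean()
    n_per_a = n / df["dap"].nunique()
    n_per_b = n / df["genotype"].nunique()
    n_per_cell = n / (df["dap"].nunique() * df["genotype"].nunique())
    ss_a = n_per_a * sum((m - grand) ** 2 for m in a_means)
    ss_b = n_per_b * sum((m - grand) ** 2 for m in b_means)
    ss_cells = n_per_cell * sum((m - grand) ** 2 for m in cells.mean())
    ss_inter = ss_cells - ss_a - ss_b
    ss_resid = sum((v - m) ** 2 for (_, g) in cells for v, m in zip(g, [g.mean()] * len(g)))
    return ss_a, ss_b, ss_inter, ss_resid


class TestOlsSimple:
    def test_perfect_line(self):
        x = np.arange(10.0)
        fit = ols_simple(x, 2 * x + 1)
        assert fit.slope == pytest.approx(2)
        assert fit.intercept == pytest.approx(1)
        assert fit.r2 == pytest.approx(1)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 7))
            x = rng.uniform(-5, 5, n)
            y = rng.uniform(-5, 5, n)
            if np.ptp(x) == 0:
                continue
            fit = ols_simple(x, y)
            slope, intercept = normal_equations_fit(x, y)
            assert fit.slope == pytest.approx(slope, rel=1e-9, abs=1e-9)
            assert fit.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-9)

    def test_r2_equals_squared_pearson(self, rng):
        x = rng.uniform(0, 1, 25)
        y = 3 * x + rng.normal(0, 0.5, 25)
        fit = ols_simple(x, y)
        assert fit.r2 == pytest.approx(fit.pearson_r**2, abs=1e-9)
        assert fit.r2 == pytest.approx(pearson(x, y) ** 2, abs=1e-9)

    @pytest.mark.parametrize(
        "genotype, trait",
        [("Yecora-Rojo", "LDW"), ("Yecora-Rojo", "BIO"), ("Seri-82", "LA")],
    )
    def test_reproduces_published_regression_rows(self, genotype, trait):
        """The SPA-predictor rows that are exactly consistent with the
        published per-genotype means."""
        fit = ols_simple(
            ref.DESTRUCTIVE_MEANS[genotype]["SPA"], ref.DESTRUCTIVE_MEANS[genotype][trait]
        )
        slope_p, _, r2_p, r_p = ref.PUBLISHED_REGRESSIONS[genotype][trait]
        assert round_half_up(100 * fit.r2, 1) == pytest.approx(r2_p)
        if genotype == "Yecora-Rojo":
            decimals = len(str(slope_p).split(".")[1])
            assert round_half_up(fit.slope, decimals) == pytest.approx(slope_p)
        assert round_half_up(fit.pearson_r, 2) == pytest.approx(r_p)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ols_simple([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPearson:
    def test_published_rgr_cross_correlations(self):
        """RGR_BIO vs RGR_SPA over the seven printed intervals."""
        for genotype, expected in ref.PUBLISHED_RGR_CORRELATIONS.items():
            r = pearson(
                ref.PUBLISHED_RGR[genotype]["SPA"], ref.PUBLISHED_RGR[genotype]["BIO"]
            )
            assert round_half_up(r, 2) == expected

    def test_perfect_anticorrelation(self):
        x = np.arange(5.0)
        assert pearson(x, -x) == pytest.approx(-1)

    def test_matches_covariance_ratio_oracle(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        num = np.mean((x - x.mean()) * (y - y.mean()))
        assert pearson(x, y) == pytest.approx(num / (x.std() * y.std()))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


def balanced_frame(rng, effects=True, reps=5):
    rows = []
    for gi, genotype in enumerate(["A", "B"]):
        for ti, dap in enumerate(ref.SCHEDULE):
            mean = (10 + 3 * ti + 4 * gi + (0.5 * ti * gi if effects else 0)) if effects else 0
            for _ in range(reps):
                rows.append(
                    {"genotype": genotype, "dap": dap, "value": mean + rng.normal()}
                )
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_ss_match_cell_means_oracle(self, rng):
        df = balanced_frame(rng)
        out = two_way_anova(df)
        ss_a, ss_b, ss_inter, ss_resid = cell_means_anova_ss(df)
        table = out.table
        assert table.loc["time point", "sum_sq"] == pytest.approx(ss_a, rel=1e-9)
        assert table.loc["genotype", "sum_sq"] == pytest.approx(ss_b, rel=1e-9)
        assert table.loc["interaction", "sum_sq"] == pytest.approx(ss_inter, rel=1e-8)
        assert table.loc["residual", "sum_sq"] == pytest.approx(ss_resid, rel=1e-9)

    def test_df_and_ss_decomposition(self, rng):
        df = balanced_frame(rng)
        out = two_way_anova(df)
        assert out.table["df"].sum() == len(df) - 1
        total_ss = ((df["value"] - df["value"].mean()) ** 2).sum()
        assert out.table["sum_sq"].sum() == pytest.approx(total_ss, rel=1e-6)
        assert 0 <= out.r2 <= 1

    def test_interaction_pvalues_uniform_under_null(self, rng):
        """With no interaction effect the interaction p-value is U(0,1)."""
        from scipy.stats import kstest

        pvals = []
        for _ in range(300):
            df = balanced_frame(rng, effects=False, reps=3)
            pvals.append(two_way_anova(df).table.loc["interaction", "p"])
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_all_equal_values_warn_and_zero_r2(self):
        df = balanced_frame(np.random.default_rng(0), reps=2)
        df["value"] = 5.0
        with pytest.warns(UserWarning, match="identical"):
            out = two_way_anova(df)
        assert out.r2 == 0

    def test_unbalanced_design_rejected(self, rng):
        df = balanced_frame(rng).iloc[:-1]
        with pytest.raises(UnbalancedDesignError):
            two_way_anova(df)

    def test_single_level_factor_rejected(self, rng):
        df = balanced_frame(rng)
        with pytest.raises(ValueError, match="two levels"):
            two_way_anova(df[df.genotype == "A"])


class TestExponentialPredictor:
    def test_exact_on_exponential_data(self):
        x = np.linspace(0, 50000, 8)
        y = 3 * np.exp(0.0001 * x)
        fit = fit_exponential_predictor(x, y)
        assert fit.a == pytest.approx(3, rel=1e-9)
        assert fit.b == pytest.approx(0.0001, rel=1e-9)
        assert fit.r2_original == pytest.approx(1)

    def test_beats_linear_fit_on_reference_biomass(self):
        """Post-heading biomass rises faster than linearly in SPA, so the
        exponential model explains more variance on the original scale."""
        spa = ref.DESTRUCTIVE_MEANS["Yecora-Rojo"]["SPA"]
        bio = ref.DESTRUCTIVE_MEANS["Yecora-Rojo"]["BIO"]
        assert fit_exponential_predictor(spa, bio).r2_original > ols_simple(spa, bio).r2

    def test_two_points_interpolated_exactly(self):
        fit = fit_exponential_predictor([1.0, 2.0], [10.0, 40.0])
        assert fit.predict([1.0, 2.0]) == pytest.approx([10.0, 40.0])

    def test_non_positive_response_rejected(self):
        with pytest.raises(ValueError):
            fit_exponential_predictor([1.0, 2.0, 3.0], [1.0, -2.0, 3.0])
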