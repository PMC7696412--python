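"""Synthetic image rendering and destructive growth-study simulation."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from wheatspa.growth import TraitSeries, fit_compound_interest, rgr_table
from wheatspa.synthetic import (
    DEFAULT_GROWTH_SPEC,
    BladeSpec,
    CanvasOverflowError,
    GenotypeParams,
    GrowthSimSpec,
    ImagingSpec,
    PlantSpec,
    expected_traits,
    plant_spec_for_area,
    render_plant,
    simulate_destructive_study,
    spa_trajectory,
)


def segment_distance(p, a, b):
    """Euclidean distance from point p to segment ab (pure python oracle)."""
    (px, py), (ax, ay), (bx, by) = p, a, b
    dx, dy = bx - ax, by - ay
    t = ((px - ax) * dx + (py - ay) * dy) / (dx * dx + dy * dy)
    t = max(0.0, min(1.0, t))
    return math.hypot(px - (ax + t * dx), py - (ay + t * dy))


class TestRenderPlant:
    def test_straight_vertical_blade_matches_analytic_footprint(self, imaging):
        """A zero-curvature thin blade is a vertical stroke of constant
        rasterized radius; every pixel can be classified independently by its
        distance to the blade's axis segment."""
        # width below the rasterization floor -> constant stroke radius 1.6 px
        length = 60 * imaging.scale  # integer pixel length
        blade = BladeSpec(length_mm=length, width_mm=2 * imaging.scale, curvature=0.0)
        spec = PlantSpec(blades=(blade,))
        noise_free = replace(imaging, fg_sd=0.0, bg_sd=0.0)
        img, mask, area = render_plant(spec, noise_free, angle_deg=0.0, seed=1)

        base_radius = blade.width_mm / (2 * imaging.scale)  # below the floor
        base_row = imaging.rows - 2 - math.ceil(base_radius)
        base_col = imaging.cols // 2
        top = (base_row - 60.0, float(base_col))
        bottom = (float(base_row), float(base_col))
        expected = np.zeros_like(mask)
        r0 = int(top[0]) - 2
        for r in range(r0, base_row + 3):
            for c in range(base_col - 3, base_col + 4):
                if segment_distance((r, c), top, bottom) <= 1.6:
                    expected[r, c] = 1
        np.testing.assert_array_equal(mask, expected)
        # zero noise -> image is exactly two-level
        assert set(np.unique(img.pixels)) == {int(noise_free.bg_mean), int(noise_free.fg_mean)}
        assert area == mask.sum() * imaging.scale**2

    def test_views_180_degrees_apart_have_identical_area(self, imaging, rng):
        spec = plant_spec_for_area(30000, imaging, rng)
        for angle in (0.0, 30.0, 75.0):
            _, m1, a1 = render_plant(spec, imaging, angle_deg=angle, seed=3)
            _, m2, a2 = render_plant(spec, imaging, angle_deg=angle + 180, seed=3)
            assert a1 == a2
            # opposite side views are mirror silhouettes
            assert m1.sum() == m2.sum()

    def test_fixed_seed_is_bitwise_deterministic(self, imaging, rng):
        spec = plant_spec_for_area(20000, imaging, rng)
        img1, mask1, _ = render_plant(spec, imaging, angle_deg=30, seed=11)
        img2, mask2, _ = render_plant(spec, imaging, angle_deg=30, seed=11)
        np.testing.assert_array_equal(img1.pixels, img2.pixels)
        np.testing.assert_array_equal(mask1, mask2)
        img3, _, _ = render_plant(spec, imaging, angle_deg=30, seed=12)
        assert np.any(img3.pixels != img1.pixels)

    def test_blade_exceeding_canvas_raises(self, imaging):
        blade = BladeSpec(length_mm=2 * imaging.rows * imaging.scale, width_mm=10)
        with pytest.raises(CanvasOverflowError):
            render_plant(PlantSpec(blades=(blade,)), imaging)

    def test_ground_truth_area_matches_mask(self, imaging, rng):
        spec = plant_spec_for_area(15000, imaging, rng)
        _, mask, area = render_plant(spec, imaging, angle_deg=90, seed=5)
        assert area == pytest.approx(mask.sum() * imaging.scale**2)


class TestGrowthSimulation:
    def test_zero_noise_replicates_equal_analytic_trajectory(self):
        spec = GrowthSimSpec(
            genotypes=DEFAULT_GROWTH_SPEC.genotypes, noise_sd=0.0, trait_noise_sd=0.0
        )
        df = simulate_destructive_study(spec)
        for g in spec.genotypes:
            for dap in spec.time_points:
                sub = df[(df.genotype == g.name) & (df.dap == dap)]
                truth = expected_traits(g, dap)
                for trait in ("LA", "LDW", "BIO", "SPA"):
                    assert sub[trait].nunique() == 1
                    assert sub[trait].iloc[0] == pytest.approx(truth[trait])

    def test_replicate_mean_converges_at_large_n(self):
        g = DEFAULT_GROWTH_SPEC.genotypes[0]
        spec = GrowthSimSpec(
            genotypes=(g,), time_points=(30,), replicates=1000, noise_sd=0.1,
            trait_noise_sd=0.0, seed=5,
        )
        df = simulate_destructive_study(spec)
        truth = expected_traits(g, 30)["SPA"]
        assert df["SPA"].mean() == pytest.approx(truth, rel=0.01)

    def test_destructive_plants_are_unique_per_time_point(self):
        df = simulate_destructive_study(DEFAULT_GROWTH_SPEC)
        assert df.groupby("plant_id")["dap"].nunique().max() == 1
        counts = df.groupby(["genotype", "dap"]).size()
        assert (counts == DEFAULT_GROWTH_SPEC.replicates).all()

    def test_longitudinal_mode_tracks_the_same_plants(self):
        spec = replace(DEFAULT_GROWTH_SPEC, longitudinal=True)
        df = simulate_destructive_study(spec)
        per_plant = df.groupby("plant_id")["dap"].nunique()
        assert (per_plant == len(spec.time_points)).all()

    def test_seed_determinism(self):
        a = simulate_destructive_study(DEFAULT_GROWTH_SPEC)
        b = simulate_destructive_study(DEFAULT_GROWTH_SPEC)
        pd.testing.assert_frame_equal(a, b)

    def test_mean_growth_monotone_and_rgr_declines(self):
        """The defaults mimic the study's qualitative patterns: means grow
        over the schedule and relative growth is fastest early on."""
        for g in DEFAULT_GROWTH_SPEC.genotypes:
            values = [expected_traits(g, d)["SPA"] for d in DEFAULT_GROWTH_SPEC.time_points]
            assert all(b > a for a, b in zip(values, values[1:]))
            series = TraitSeries(
                "SPA", "mm2",
                tuple(float(d) for d in DEFAULT_GROWTH_SPEC.time_points), tuple(values),
            )
            rates = [iv.value for iv in rgr_table(series)]
            assert all(b < a for a, b in zip(rates, rates[1:]))

    def test_biomass_departs_from_linearity_after_heading(self):
        """Post-heading the BIO/SPA ratio inflates, so an exponential fit
        explains the simulated means better than a line."""
        from wheatspa.stats import fit_exponential_predictor, ols_simple

        g = DEFAULT_GROWTH_SPEC.genotypes[0]  # heads mid-schedule
        spa = [expected_traits(g, d)["SPA"] for d in DEFAULT_GROWTH_SPEC.time_points]
        bio = [expected_traits(g, d)["BIO"] for d in DEFAULT_GROWTH_SPEC.time_points]
        ratio = np.array(bio) / np.array(spa)
        assert ratio[-1] > 2 * ratio[0]
        assert fit_exponential_predictor(spa, bio).r2_original > ols_simple(spa, bio).r2

    def test_compound_interest_recovery_before_deceleration(self):
        """With the plateau pushed far away the early trajectory is pure
        exponential; fitting the first three time-point means recovers the
        simulated rate within 5%."""
        g = GenotypeParams(
            name="exp", spa_anchor_mm2=1000, rate=0.25, spa_max_mm2=1e9, heading_dap=100
        )
        spec = GrowthSimSpec(genotypes=(g,), replicates=5, noise_sd=0.1, seed=1)
        df = simulate_destructive_study(spec)
        means = df[df.dap <= 30].groupby("dap")["SPA"].mean()
        series = TraitSeries(
            "SPA", "mm2", tuple(float(d) for d in means.index), tuple(means.values)
        )
        assert fit_compound_interest(series).r == pytest.approx(0.25, rel=0.05)

    def test_trajectory_is_exponential_early(self):
        g = GenotypeParams(
            name="exp", spa_anchor_mm2=1000, rate=0.2, spa_max_mm2=1e9, heading_dap=100
        )
        t = np.array([21.0, 25.0, 30.0])
        np.testing.assert_allclose(
            spa_trajectory(g, t), 1000 * np.exp(0.2 * (t - 21)), rtol=1e-4
        )
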