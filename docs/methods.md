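# Methods

## Segmentation model

A chlorophyll-fluorescence side view is modeled as a bright plant
silhouette on a dark background, so segmentation is a single global
threshold plus cleanup:

* **Otsu threshold.** Computed on the full 2^bit-depth gray-level
  histogram (256 bins for 8-bit; deeper images are thresholded on their
  native range, never rescaled). A candidate level t splits levels into
  background (< t) and foreground (≥ t); the returned level maximizes the
  between-class variance ω₀(t)ω₁(t)(μ₀(t)−μ₁(t))², with ties broken by
  the **lowest** maximizing level — deterministic and conventional. The
  "pixels below the threshold are background" rule is applied literally,
  so pixels exactly at the threshold are foreground. A histogram with
  fewer than two populated levels has no foreground/background split and
  raises a degenerate-histogram error rather than returning an arbitrary
  level. Note the off-by-one relative to scikit-image's convention
  (foreground strictly greater than the returned value); the two agree to
  within one gray level.
* **Morphology.** Opening then closing with disk structuring elements,
  radius 1 px each by default. The source imaging protocol prescribes
  opening and closing but not element sizes; radius 1 is the smallest
  cleanup that removes single-pixel speckle and fills pinholes without
  eroding thin wheat leaves, and both radii are configurable (0 = no-op).
  An optional keep-largest-component step exists but is **off** by
  default, since the baseline pipeline relies on morphology alone.

Coordinates are row-major with the origin at top-left.

## Traits

SPA is the foreground pixel count; height and width are the inclusive
vertical/horizontal extents of the axis-aligned enclosing rectangle.
Height is taken as the vertical side of that rectangle (not its longest
side) — the natural reading for upright plants on a rotation stage.
Calibration is a single scalar s (mm per pixel) per imaging setup:
lengths multiply by s, areas by s². The per-plant SPA at a time point is
the arithmetic mean over the available rotational views; twelve views at
30° steps are nominal, and a deviating count aggregates anyway with a
warning (robustness to missing frames).

## Growth rates

Two RGR conventions coexist in the literature and differ materially at
the growth rates seen here:

* **Simple ratio** (the default): RGR = (W₂−W₁)/(W₁·Δt). This is the
  convention the reference study's printed interval tables follow — the
  package reproduces all 21 printed Yecora-Rojo entries from the printed
  means exactly at printed precision under this formula, which is the
  strongest available evidence for the convention.
* **Log difference** (`classical_rgr`): ln(W₂/W₁)/Δt, exact under
  exponential growth and agreeing with the simple ratio to first order
  for small relative increments.

Dry-weight rates are scaled to mg g⁻¹ d⁻¹ (factor 1000); area rates stay
bare fractions (mm² mm⁻² d⁻¹). The compound-interest law W(t) = W₀·e^{rt}
is fitted by OLS of ln W on t (W₀ = e^intercept, r = slope); with two
points this reduces to the closed form r = ln(W₁/W₀)/Δt. Log-space
fitting makes the estimator exact on noise-free exponential data and
unbiased in log space under multiplicative lognormal noise; both
properties are asserted in the suite.

RGR on real destructive data is computed on per-genotype means at each
date — destructive sampling provides no paired plants across dates. The
per-plant mode exists for longitudinal (non-destructive) tables only.

## Validation statistics

Simple OLS (via `scipy.stats.linregress`) reports slope, intercept,
R² = 1−SS_res/SS_tot, and the signed Pearson r; for a single predictor
R² ≡ r², asserted at 1e-9. The SPA-predictor regressions are fitted on
the **8 per-genotype time-point means**: recomputation confirms this is
what the published regression rows contain (e.g. LDW on SPA for
Yecora-Rojo: slope 0.066, intercept 149.1, R² 98.4%), and per-plant raw
data is not published. Per-plant fitting is available for synthetic data.

Two-way ANOVA (value ~ time point × genotype, via statsmodels `anova_lm`,
type-I SS) is restricted to balanced layouts, where type-I SS is
order-invariant and the components sum exactly to the total SS; unbalanced
layouts are rejected explicitly rather than silently approximated, since
the study design is balanced. The model R² is
(SS_time+SS_geno+SS_inter)/SS_total, reported as 0 with a warning when all
values are identical.

The post-heading biomass departure is modeled with a log-linear
exponential predictor y = a·e^{bx} (OLS of ln y on x) — a deterministic
closed-form fit matching the stated exponential shape; both the log-scale
R² and the original-scale pseudo-R² (1−SS_res/SS_tot on back-transformed
predictions) are reported, and on the reference Yecora-Rojo means the
exponential pseudo-R² (95.7%) exceeds the linear R² (85.6%).

## Published reference values and their consistency

The embedded published tables carry one known internal inconsistency:
every Yecora-Rojo derived value recomputes exactly from the Yecora-Rojo
means, but several Seri-82 interval RGR entries do not (e.g. biomass
21–25 DAP derives as 366.4 against a printed 349.3), and the Seri-82
LDW/BIO regression slopes differ in the third decimal. How those entries
were derived (possibly per-plant averaging on unpublished raw data) is not
stated in the source. The package therefore anchors its exact-arithmetic
reproduction on Yecora-Rojo plus the Seri-82 LA row (which does
reproduce), keeps the printed Seri-82 values embedded and uses them where
the source itself does (the RGR cross-correlations 0.97/0.91 are computed
from the printed interval tables and reproduce for both genotypes), and
documents rather than "corrects" the discrepancy. Comparisons against
printed values round half away from zero at the printed number of
decimals, matching how the tables were evidently rounded (372.28 → 372.3).

The published full-model ANOVA R² values and the figure-only panel fits
require per-plant raw data that cannot be reconstructed from means ± SE;
they are covered qualitatively by the replicated-ANOVA property test on
synthetic data instead.

## Synthetic data generator

**Images.** A plant is a set of leaf blades: tapered strokes of quadratic
lateral curvature rising from a common base, each with its own azimuth,
length, width and tiller offset. Under side projection at camera angle θ a
blade's lateral displacement is foreshortened by cos(azimuth−θ), so views
180° apart are mirror images with identical area — a rendering invariant
the tests exploit. Foreground/background intensities are drawn from
normal distributions (defaults 180±10 vs 30±10 on 8-bit) and clipped; the
exact pre-noise mask and foreground area are returned as ground truth.
Default canvas 320×240 at 3 mm/px covers an ~85 cm plant. Strokes keep a
rasterization floor of ≈1.6 px half-width so that blade tips remain
resolvable objects rather than sub-pixel chains; geometry for a requested
silhouette area is drawn randomly, then deterministically rescaled
(lengths first, stroke width once lengths hit the canvas bound) using
calibration renders, landing the realized area within a few percent of
target across the study's 12 000–115 000 mm² range.

**Growth tables.** SPA follows a logistic trajectory anchored at 21 DAP,
S(t) = K/(1+(K/S₂₁−1)e^{−r(t−21)}): effectively exponential at rate r
early (compound-interest regime) and decelerating toward the plateau K,
matching the reference pattern of interval RGR that is highest in the
earliest interval and declines monotonically. The two default genotypes
mimic the reference magnitudes — an early header (S₂₁ = 12 500 mm²,
r = 0.20 d⁻¹, K = 88 000 mm², heading 39 DAP) and a late header
(S₂₁ = 10 900, r = 0.18, K = 118 000, heading 51 DAP). Leaf area and leaf
dry weight are linear in SPA (0.011 cm²/mm² and 0.066 mg/mm² for the
early header); biomass is linear in SPA before heading and inflates by
10%/day afterwards, reproducing the post-heading super-linear biomass–SPA
relation (spikes are denser than leaves). Replicates are independent
plants per date (destructive semantics; no plant id recurs), with
**mean-one** lognormal noise — a shared per-plant size factor (sd 0.10 on
the log scale) times smaller independent per-trait factors (sd 0.03) — so
replicate means are unbiased for the trajectory. A longitudinal mode
reuses plants and their size factors across dates for per-plant RGR
testing. All generators are seed-deterministic.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: leaf occlusion and self-shadowing, spike/head
geometry (only the scalar biomass inflation), illumination gradients and
specular artifacts, soil/pot pixels, registration errors between views,
and any genotype × environment structure beyond two fixed parameter sets.
Segmentation accuracy on these clean two-mode images is an upper bound,
not an estimate, of field performance.

## Numerical choices

* Otsu ties → lowest level; degenerate histograms raise.
* Morphology radius 0 is an exact no-op; empty masks pass through.
* Geometric traits on empty masks raise (no silent zeros for extents;
  SPA of an empty mask is 0).
* Printed-value comparisons: half-up rounding at printed decimals.
* ANOVA: balanced-only, type-I; constant data → R² 0 with warning.
* Exponential fits require strictly positive values (log transform).
* Seeds: every stochastic component takes an explicit integer seed;
  derived seeds stay below 2³¹.

## Problem sizes

The suite and the acceptance script size their simulations for a desk
run: 100–200 random histograms for the Otsu oracle, two rendered plants ×
12 views for end-to-end recovery, 300–500 simulated null datasets
(2 genotypes × 8 dates × 3 replicates) for ANOVA calibration, and 100
noisy trajectories for rate recovery. The analysis drivers render one
replicate per date (192 images); the trait tables keep the full five.
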