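# wheatspa

Image-based growth analysis for wheat: from side-view plant silhouettes to
relative growth rates, with the statistics that justify replacing
destructive sampling with a camera.

## The problem

Classical growth analysis of wheat is destructive: measuring leaf area
(LA, cm²), leaf dry weight (LDW, mg) and above-ground biomass (BIO, mg)
kills the plant, so an eight-date growth curve with five replicates costs
forty plants per genotype and still yields only coarse temporal
resolution. High-throughput phenotyping replaces most of that with
imaging: a plant on a rotation stage is photographed from 12 azimuthal
angles (30° steps), each fluorescence-style image is segmented into a
binary silhouette, and the **side-projected area**

SPA = Σ mask pixels × s² (mm², with s the mm-per-pixel calibration),

averaged over the 12 views, serves as a non-destructive surrogate for the
destructive traits.

This package implements the full computational chain and its validation:

1. **Segmentation** — Otsu's threshold on the gray-level histogram
   (maximizing the between-class variance σ²_B(t) = ω₀ω₁(μ₀−μ₁)²),
   binarization with pixels below the threshold as background, then
   morphological opening and closing with disk structuring elements.
2. **Traits** — SPA as the foreground pixel sum, height/width as the
   enclosing rectangle, scalar mm-per-pixel calibration, 12-angle
   aggregation.
3. **Growth** — interval relative growth rate in the simple-ratio
   convention RGR = (W₂−W₁)/(W₁·Δt) (mg g⁻¹ d⁻¹ for dry weights,
   mm² mm⁻² d⁻¹ for SPA), the classical log-difference rate
   ln(W₂/W₁)/Δt, and least-squares fitting of the compound-interest law
   W(t) = W₀·e^{rt} in log space.
4. **Statistics** — OLS regressions of each destructive trait on SPA,
   Pearson correlations between RGR series, balanced two-way ANOVA
   (time point × genotype with interaction, type-I SS), and a log-linear
   exponential predictor y = a·e^{bx} for the post-heading regime where
   the linear SPA→biomass relation breaks down.
5. **Synthetic data** — a seeded generator of fluorescence-style plant
   images with exact ground-truth masks, and of destructive study tables
   (2 genotypes × 8 dates × 5 independent plants) with logistic growth
   trajectories and post-heading biomass inflation, so every stage is
   testable without chamber data.

The published per-genotype trait means of the reference study (two spring
wheat genotypes, Yecora-Rojo and Seri-82, sampled at 21–53 days after
planting) are embedded in `wheatspa.reference_data` and drive the
reproduction checks.

## Worked example

```sh
wheatspa reproduce
```

recomputes every derived number from the embedded means. Excerpt of the
actual output:

```
Interval RGR, computed from trait means vs printed:
  Yecora-Rojo  RGR_LDW  21-25 DAP: computed 309 vs printed 309  [ok]
  ...
  Yecora-Rojo  RGR_BIO  21-25 DAP: computed 372.3 vs printed 372.3  [ok]
  Yecora-Rojo  RGR_SPA  49-53 DAP: computed 0.006 vs printed 0.006  [ok]
SPA-predictor regressions on time-point means vs printed:
  Yecora-Rojo  LDW  slope 0.0660 R2 98.4% (printed 0.066 / 98.4%)  [ok]
  Yecora-Rojo  BIO  slope 0.5709 R2 85.6% (printed 0.5709 / 85.6%)  [ok]
RGR_BIO ~ RGR_SPA cross-validation:
  Yecora-Rojo  r 0.97 R2 93% (printed r 0.97)  [ok]
  Seri-82      r 0.91 R2 83% (printed r 0.91)  [ok]
reproduction anchors: all matched
```

Reading: the first biomass interval (21→25 DAP, 920→2290 mg) gives
(2290−920)/(920·4)·1000 = 372.3 mg g⁻¹ d⁻¹; rates fall roughly fivefold
by the last interval as growth decelerates. SPA-derived RGR tracks
biomass RGR with r = 0.97 (R² ≈ 93%) — the quantitative case for the
imaging surrogate.

The end-to-end image pipeline runs as a sequence of analysis drivers:

```sh
python analysis/01_simulate_study.py     # synthetic study + rendered images
python analysis/02_segment_images.py    # segment, extract, aggregate SPA
python analysis/03_growth_rates.py      # RGR tables + exponential fits
python analysis/04_validate_surrogates.py
python analysis/05_reproduce_published.py
```

On the default synthetic series the segmented, 12-angle-averaged SPA lands
within ~2% of the renderer's ground truth for every plant (printed as
`SPA recovery vs ground truth: mean 0.75%, worst 1.74% over 16 plants`),
and the two-way ANOVA on the replicated table shows the same significance
pattern as the reference study. Tables land under `results/`; rendered
images under `scratch/`.

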