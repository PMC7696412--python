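"""Synthetic fluorescence images and destructive growth tables with known truth.

Two generators make every pipeline stage testable without real chamber data:

* :func:`render_plant` rasterizes a stylized wheat plant — thin, tapered,
  quadratically curved blades fanning out in azimuth from a common base —
  as a side-view silhouette at a given camera angle, then draws foreground
  and background intensities from normal distributions.  The exact binary
  mask and foreground area are returned as ground truth.

* :func:`simulate_destructive_study` emulates the destructive sampling
  design (genotypes × time points × independent replicate plants) with
  per-genotype logistic trajectories for side-projected area (SPA):
  early growth is effectively exponential (compound-interest law) and
  decelerates toward a plateau.  Leaf area and leaf dry weight scale
  linearly with SPA; biomass scales linearly before heading and inflates
  super-linearly afterwards, mimicking the higher specific weight of
  spikes during grain fill.

All randomness flows from explicit integer seeds; identical spec + seed
gives identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .segmentation import GrayImage

__all__ = [
    "BladeSpec",
    "PlantSpec",
    "ImagingSpec",
    "GenotypeParams",
    "GrowthSimSpec",
    "CanvasOverflowError",
    "DEFAULT_GROWTH_SPEC",
    "render_plant",
    "plant_spec_for_area",
    "expected_traits",
    "spa_trajectory",
    "simulate_destructive_study",
    "simulate_imaging_series",
]


class CanvasOverflowError(ValueError):
    """Blade geometry extends beyond the image canvas."""


@dataclass(frozen=True)
class BladeSpec:
    """One leaf blade: a tapered stroke of ``length_mm`` bending sideways.

    ``curvature`` is the dimensionless lateral tip displacement as a
    fraction of blade length (0 = straight vertical); ``azimuth_deg`` is the
    compass direction of the bend in the horizontal plane.
    """

    length_mm: float
    width_mm: float
    curvature: float = 0.0
    azimuth_deg: float = 0.0
    base_radius_mm: float = 0.0  # tiller offset from the plant axis, along azimuth

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.width_mm <= 0:
            raise ValueError("blade length and width must be positive")
        if not 0 <= self.azimuth_deg < 360:
            raise ValueError("azimuth must lie in [0, 360)")
        if self.base_radius_mm < 0:
            raise ValueError("base radius must be non-negative")


@dataclass(frozen=True)
class PlantSpec:
    blades: tuple[BladeSpec, ...]
    growth_stage: float = 1.0  # 0..1, informational

    def __post_init__(self) -> None:
        if len(self.blades) < 1:
            raise ValueError("a plant needs at least one blade")
        if not 0 <= self.growth_stage <= 1:
            raise ValueError("growth_stage must lie in [0, 1]")


@dataclass(frozen=True)
class ImagingSpec:
    """Virtual imaging booth: canvas size, calibration, intensities, angles."""

    rows: int = 320
    cols: int = 240
    scale: float = 3.0  # mm per pixel
    fg_mean: float = 180.0
    fg_sd: float = 10.0
    bg_mean: float = 30.0
    bg_sd: float = 10.0
    bit_depth: int = 8
    angles: tuple[float, ...] = tuple(range(0, 360, 30))

    def __post_init__(self) -> None:
        if self.fg_mean <= self.bg_mean:
            raise ValueError("foreground mean must exceed background mean")
        if self.fg_sd < 0 or self.bg_sd < 0:
            raise ValueError("intensity sds must be non-negative")
        if not 0 <= self.fg_mean < 2**self.bit_depth:
            raise ValueError("foreground mean not representable at bit depth")


def _paint_disk(mask: np.ndarray, row: float, col: float, radius_px: float) -> None:
    r0 = int(round(row))
    c0 = int(round(col))
    if radius_px < 0.5:
        mask[r0, c0] = True
        return
    rad = int(math.ceil(radius_px))
    rr, cc = np.ogrid[r0 - rad : r0 + rad + 1, c0 - rad : c0 + rad + 1]
    patch = (rr - row) ** 2 + (cc - col) ** 2 <= radius_px**2
    mask[r0 - rad : r0 + rad + 1, c0 - rad : c0 + rad + 1] |= patch


def render_plant(
    plant: PlantSpec,
    imaging: ImagingSpec,
    angle_deg: float = 0.0,
    seed: int = 0,
) -> tuple[GrayImage, np.ndarray, float]:
    """Render one side view; returns (image, ground-truth mask, true area mm²).

    Each blade is sampled densely along its arc; its lateral (azimuthal)
    displacement is foreshortened by cos(azimuth − camera angle) under side
    projection, so views 180° apart are mirror images with identical area.
    Intensities are drawn per pixel from the foreground/background normals
    and clipped to the bit depth.
    """
    mask = np.zeros((imaging.rows, imaging.cols), dtype=bool)
    base_radius = max(b.width_mm for b in plant.blades) / (2 * imaging.scale)
    base_row = imaging.rows - 2 - math.ceil(base_radius)
    base_col = imaging.cols // 2

    for blade in plant.blades:
        length_px = blade.length_mm / imaging.scale
        n_steps = max(8, int(1.5 * length_px))  # ≲0.7 px steps keep strokes gap-free
        proj = math.cos(math.radians(blade.azimuth_deg - angle_deg))
        for s in np.linspace(0.0, 1.0, n_steps):
            # vertical rise flattens slightly as the blade bends out
            z_mm = blade.length_mm * s * (1.0 - 0.3 * blade.curvature * s**2)
            u_mm = blade.base_radius_mm + blade.length_mm * blade.curvature * s**2
            row = base_row - z_mm / imaging.scale
            col = base_col + (u_mm * proj) / imaging.scale
            # linear taper with a floor so tips stay a few pixels wide
            radius_px = max(
                blade.width_mm * (1.0 - 0.7 * s) / (2 * imaging.scale), 1.6
            )
            margin = math.ceil(radius_px)
            r0, c0 = int(round(row)), int(round(col))
            if not (
                margin <= r0 < imaging.rows - margin
                and margin <= c0 < imaging.cols - margin
            ):
                raise CanvasOverflowError(
                    f"blade of {blade.length_mm:.0f} mm exceeds the "
                    f"{imaging.rows}x{imaging.cols} canvas at {imaging.scale} mm/px"
                )
            _paint_disk(mask, row, col, radius_px)

    rng = np.random.default_rng(seed)
    pixels = np.where(
        mask,
        rng.normal(imaging.fg_mean, imaging.fg_sd, mask.shape),
        rng.normal(imaging.bg_mean, imaging.bg_sd, mask.shape),
    )
    pixels = np.clip(np.rint(pixels), 0, 2**imaging.bit_depth - 1).astype(np.int64)
    image = GrayImage(pixels, bit_depth=imaging.bit_depth)
    true_area_mm2 = float(mask.sum()) * imaging.scale**2
    return image, mask.astype(np.uint8), true_area_mm2


def plant_spec_for_area(
    target_spa_mm2: float,
    imaging: ImagingSpec,
    rng: np.random.Generator,
    growth_stage: float = 1.0,
) -> PlantSpec:
    """Draw a random plant whose rendered silhouette area ≈ ``target_spa_mm2``.

    Blade count and length grow with the target; after drawing random
    geometry, one calibration render measures the actual silhouette and
    rescales blade widths so the mean-over-angles area lands near the
    target (rasterization and blade overlap keep it approximate).
    """
    if target_spa_mm2 <= 0:
        raise ValueError("target area must be positive")
    max_len = 0.72 * imaging.rows * imaging.scale
    min_len = 10 * imaging.scale
    width0 = 10.0 * imaging.scale  # ~10 px wide at the base
    max_base = 0.18 * imaging.cols * imaging.scale
    n_blades = max(2, min(12, int(round(target_spa_mm2 / (0.55 * width0 * max_len)))))
    nominal0 = min(target_spa_mm2 / (0.55 * width0 * n_blades), max_len)

    lat_max = (imaging.cols // 2 - 10) * imaging.scale  # lateral clearance from the axis

    def draw(length_scale: float, width_mm: float) -> PlantSpec:
        blades = []
        for i in range(n_blades):
            length = float(
                np.clip(nominal0 * length_scale * rng.uniform(0.85, 1.15), min_len, max_len)
            )
            azimuth = (360.0 * i / n_blades + rng.uniform(-12, 12)) % 360.0
            base = rng.uniform(0.0, max_base)
            curvature = min(rng.uniform(0.15, 0.55), max(0.0, (lat_max - base) / length))
            blades.append(
                BladeSpec(
                    length_mm=length,
                    width_mm=width_mm,
                    curvature=curvature,
                    azimuth_deg=azimuth,
                    base_radius_mm=base,
                )
            )
        return PlantSpec(blades=tuple(blades), growth_stage=growth_stage)

    # Deterministic size calibration on the same random geometry: rescale blade
    # lengths toward the target area; once lengths hit the canvas cap, grow the
    # stroke width instead (area is length-linear but width-insensitive below
    # the rasterization floor).
    state = rng.bit_generator.state
    length_scale, width = 1.0, width0
    plant = draw(length_scale, width)
    for _ in range(3):
        areas = [
            render_plant(plant, imaging, angle_deg=a, seed=0)[2] for a in (0.0, 90.0)
        ]
        f = float(np.clip(target_spa_mm2 / max(np.mean(areas), 1e-9), 0.25, 4.0))
        len_cap = max_len / (nominal0 * length_scale)
        applied = min(f, len_cap)
        length_scale *= applied
        if f > applied:
            width = min(width * f / applied, 12.0 * imaging.scale)
        rng.bit_generator.state = state
        plant = draw(length_scale, width)
    return plant


# ---------------------------------------------------------------------------
# Destructive growth-study simulation


@dataclass(frozen=True)
class GenotypeParams:
    """Per-genotype growth and allometry parameters.

    SPA follows a logistic trajectory anchored at ``anchor_dap``:
    early relative growth ≈ ``rate`` per day, plateauing at ``spa_max``.
    ``bio_inflation`` is the per-day super-linear inflation of the
    biomass/SPA ratio after ``heading_dap`` (spikes are denser than leaves).
    Allometry units: la_per_spa cm²/mm², ldw_per_spa and bio_per_spa mg/mm².
    """

    name: str
    spa_anchor_mm2: float
    rate: float
    spa_max_mm2: float
    heading_dap: float
    bio_inflation: float = 0.10
    la_per_spa: float = 0.011
    ldw_per_spa: float = 0.066
    bio_per_spa: float = 0.15
    anchor_dap: float = 21.0

    def __post_init__(self) -> None:
        if min(self.spa_anchor_mm2, self.rate, self.spa_max_mm2) <= 0:
            raise ValueError("rates and sizes must be positive")
        if self.spa_anchor_mm2 >= self.spa_max_mm2:
            raise ValueError("anchor SPA must lie below the plateau")


@dataclass(frozen=True)
class GrowthSimSpec:
    """Study design: genotypes × time points × replicate plants.

    ``noise_sd`` is the log-scale sd of the shared plant-size factor (one
    independent draw per plant — destructive sampling semantics);
    ``trait_noise_sd`` adds smaller independent per-trait measurement
    noise.  Both lognormal factors are mean-one, so replicate means are
    unbiased for the underlying trajectory.  ``longitudinal=True`` switches
    to a non-destructive mode in which the same plants (and their size
    factors) persist across all time points.
    """

    genotypes: tuple[GenotypeParams, ...]
    time_points: tuple[float, ...] = (21, 25, 30, 35, 39, 44, 49, 53)
    replicates: int = 5
    noise_sd: float = 0.10
    trait_noise_sd: float = 0.03
    seed: int = 0
    longitudinal: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.noise_sd < 0 or self.trait_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        if any(b <= a for a, b in zip(self.time_points, self.time_points[1:])):
            raise ValueError("time points must be strictly increasing")


def _default_genotypes() -> tuple[GenotypeParams, ...]:
    return (
        GenotypeParams(
            name="G-early",
            spa_anchor_mm2=12500,
            rate=0.20,
            spa_max_mm2=88000,
            heading_dap=39,
            la_per_spa=0.011,
            ldw_per_spa=0.066,
            bio_per_spa=0.15,
        ),
        GenotypeParams(
            name="G-late",
            spa_anchor_mm2=10900,
            rate=0.18,
            spa_max_mm2=118000,
            heading_dap=51,
            la_per_spa=0.016,
            ldw_per_spa=0.100,
            bio_per_spa=0.14,
        ),
    )


DEFAULT_GROWTH_SPEC = GrowthSimSpec(genotypes=_default_genotypes())


def spa_trajectory(g: GenotypeParams, dap) -> np.ndarray:
    """Logistic SPA trajectory (mm²): exponential at rate ``g.rate`` early on."""
    t = np.asarray(dap, dtype=float) - g.anchor_dap
    k, s0 = g.spa_max_mm2, g.spa_anchor_mm2
    return k / (1.0 + (k / s0 - 1.0) * np.exp(-g.rate * t))


def expected_traits(g: GenotypeParams, dap: float) -> dict[str, float]:
    """Noise-free trait values at one time point."""
    spa = float(spa_trajectory(g, dap))
    post = max(0.0, dap - g.heading_dap)
    return {
        "SPA": spa,
        "LA": g.la_per_spa * spa,
        "LDW": g.ldw_per_spa * spa,
        "BIO": g.bio_per_spa * spa * (1.0 + g.bio_inflation * post),
    }


def _lognormal_factor(rng: np.random.Generator, sd: float, size=None):
    """Mean-one multiplicative noise: exp(N(-sd²/2, sd))."""
    if sd == 0:
        return np.ones(size) if size else 1.0
    return np.exp(rng.normal(-0.5 * sd**2, sd, size))


def simulate_destructive_study(spec: GrowthSimSpec = DEFAULT_GROWTH_SPEC) -> pd.DataFrame:
    """Simulate the trait table: genotype, plant_id, dap, LA, LDW, BIO, SPA.

    In the default destructive mode each (genotype, time point, replicate)
    is a fresh independent plant — no plant_id appears at two time points.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    for g in spec.genotypes:
        if spec.longitudinal:
            plant_factors = _lognormal_factor(rng, spec.noise_sd, spec.replicates)
        for ti, dap in enumerate(spec.time_points):
            truth = expected_traits(g, dap)
            for rep in range(spec.replicates):
                if spec.longitudinal:
                    factor = plant_factors[rep]
                    plant_id = f"{g.name}-p{rep + 1}"
                else:
                    factor = _lognormal_factor(rng, spec.noise_sd)
                    plant_id = f"{g.name}-t{ti + 1}-p{rep + 1}"
                row = {"genotype": g.name, "plant_id": plant_id, "dap": dap}
                for trait in ("LA", "LDW", "BIO", "SPA"):
                    eps = _lognormal_factor(rng, spec.trait_noise_sd)
                    row[trait] = truth[trait] * factor * eps
                rows.append(row)
    return pd.DataFrame(rows)


def simulate_imaging_series(
    growth: GrowthSimSpec,
    imaging: ImagingSpec,
    outdir,
) -> pd.DataFrame:
    """Render the full imaging series for a simulated study.

    For every plant × time point in :func:`simulate_destructive_study`, one
    random plant geometry is drawn to match that plant's simulated SPA and
    rendered at each booth angle.  PNG images, a ``manifest.csv`` linking
    files to ground truth, and the trait table ``traits.csv`` are written
    under ``outdir``; the manifest frame is returned.
    """
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    traits = simulate_destructive_study(growth)
    records = []
    for i, plant in traits.iterrows():
        stage = min(1.0, plant["SPA"] / max(g.spa_max_mm2 for g in growth.genotypes))
        rng = np.random.default_rng(np.random.SeedSequence([growth.seed, 104729, i]))
        spec = plant_spec_for_area(plant["SPA"], imaging, rng, growth_stage=stage)
        for j, angle in enumerate(imaging.angles):
            seed = np.random.SeedSequence([growth.seed, 15485863, i, j]).generate_state(1)[0]
            image, mask, true_mm2 = render_plant(spec, imaging, angle_deg=angle, seed=int(seed))
            fname = f"{plant['plant_id']}_d{int(plant['dap']):02d}_a{int(angle):03d}.png"
            iio.imwrite(outdir / fname, image.pixels.astype(np.uint8))
            records.append(
                {
                    "file": fname,
                    "genotype": plant["genotype"],
                    "plant_id": plant["plant_id"],
                    "dap": plant["dap"],
                    "angle_deg": angle,
                    "true_spa_px": int(mask.sum()),
                    "true_spa_mm2": true_mm2,
                    "target_spa_mm2": plant["SPA"],
                }
            )
    manifest = pd.DataFrame(records)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    traits.to_csv(outdir / "traits.csv", index=False)
    return manifest
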