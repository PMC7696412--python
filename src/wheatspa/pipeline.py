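"""Batch drivers tying the modules together over files and tables.

These functions are the computational core of the command-line interface:
segment a directory of side-view images into per-view geometry and
per-plant aggregated SPA; derive interval RGR tables and exponential
growth fits from a trait table; and run the validation statistics
(SPA-predictor regressions, RGR cross-correlation, two-way ANOVA).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .growth import TraitSeries, fit_compound_interest, rgr_table
from .segmentation import (
    DEFAULT_MORPHOLOGY,
    MorphologyConfig,
    gray_histogram,
    otsu_threshold,
    read_gray_image,
    segment,
)
from .stats import ols_simple, pearson, two_way_anova
from .traits import Calibration, aggregate_angles, calibrate, measure

__all__ = [
    "process_image_dir",
    "growth_report",
    "validation_report",
    "TRAIT_COLUMNS",
]

TRAIT_COLUMNS = ("LA", "LDW", "BIO", "SPA")

_FILE_PATTERN = re.compile(
    r"^(?P<plant_id>.+?)_d(?P<dap>\d+)_a(?P<angle>\d+)\.(png|tif|tiff)$", re.IGNORECASE
)


def _file_metadata(images_dir: Path) -> dict[str, dict]:
    """Per-file plant/time/angle metadata, from manifest.csv when present."""
    manifest_path = images_dir / "manifest.csv"
    if manifest_path.exists():
        manifest = pd.read_csv(manifest_path)
        return {
            row["file"]: {
                "genotype": row.get("genotype", ""),
                "plant_id": row["plant_id"],
                "dap": float(row["dap"]),
                "angle_deg": float(row["angle_deg"]),
            }
            for _, row in manifest.iterrows()
        }
    meta = {}
    for path in images_dir.iterdir():
        m = _FILE_PATTERN.match(path.name)
        if m:
            plant_id = m["plant_id"]
            genotype = plant_id.split("-t")[0] if "-t" in plant_id else plant_id
            meta[path.name] = {
                "genotype": genotype,
                "plant_id": plant_id,
                "dap": float(m["dap"]),
                "angle_deg": float(m["angle"]),
            }
    return meta


def process_image_dir(
    images_dir,
    cal: Calibration,
    cfg: MorphologyConfig = DEFAULT_MORPHOLOGY,
    log=None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Segment every image in a directory and extract calibrated geometry.

    Returns (per-view geometry frame, per-plant aggregated frame, errors).
    Files that fail to read or segment are reported and skipped; the run
    continues.
    """
    images_dir = Path(images_dir)
    meta = _file_metadata(images_dir)
    if not meta:
        raise FileNotFoundError(f"no recognizable plant images in {images_dir}")

    rows, errors = [], []
    views: dict[tuple, list] = {}
    for fname in sorted(meta):
        info = meta[fname]
        try:
            image = read_gray_image(images_dir / fname)
            threshold = otsu_threshold(gray_histogram(image))
            mask = segment(image, cfg)
            geom = calibrate(measure(mask, angle_deg=info["angle_deg"]), cal)
        except Exception as exc:  # noqa: BLE001 - per-file isolation is the contract
            errors.append(f"{fname}: {exc}")
            continue
        if log is not None:
            log(f"{fname}: threshold={threshold} spa_px={geom.spa_px}")
        views.setdefault((info["genotype"], info["plant_id"], info["dap"]), []).append(geom)
        rows.append(
            {
                **info,
                "file": fname,
                "threshold": threshold,
                "spa_px": geom.spa_px,
                "spa_mm2": geom.spa_mm2,
                "height_mm": geom.height_mm,
                "width_mm": geom.width_mm,
            }
        )
    geometry = pd.DataFrame(rows)
    if geometry.empty:
        return geometry, geometry, errors

    agg_rows = []
    for (genotype, plant_id, dap) in sorted(views):
        plant_views = views[(genotype, plant_id, dap)]
        agg = aggregate_angles(plant_views)
        agg_rows.append(
            {
                "genotype": genotype,
                "plant_id": plant_id,
                "dap": dap,
                "SPA": agg.spa_mm2,
                "n_views": agg.n_views,
                "height_mm": float(
                    sum(v.height_mm for v in plant_views) / len(plant_views)
                ),
            }
        )
    return geometry, pd.DataFrame(agg_rows), errors


def _mean_series(traits: pd.DataFrame, genotype: str, trait: str) -> TraitSeries:
    sub = traits[traits["genotype"] == genotype]
    means = sub.groupby("dap")[trait].mean().sort_index()
    return TraitSeries(
        trait=trait,
        unit="",
        dap=tuple(float(d) for d in means.index),
        values=tuple(float(v) for v in means.values),
        level="genotype-mean",
    )


def growth_report(
    traits: pd.DataFrame, per_plant: bool = False
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Interval RGR table and compound-interest fits from a trait table.

    By default rates are computed on per-genotype means at each time point
    (the only option under destructive sampling).  ``per_plant=True``
    computes per-plant rates and requires a longitudinal table in which
    each plant appears at every time point.
    """
    present = [c for c in TRAIT_COLUMNS if c in traits.columns]
    if not present:
        raise ValueError(f"trait table must contain at least one of {TRAIT_COLUMNS}")
    rgr_rows, fit_rows = [], []
    if per_plant:
        groups = [(key, grp) for key, grp in traits.groupby(["genotype", "plant_id"])]
    else:
        groups = [((g, None), None) for g in traits["genotype"].unique()]

    for (genotype, plant_id), grp in groups:
        for trait in present:
            if per_plant:
                sub = grp.sort_values("dap")
                series = TraitSeries(
                    trait=trait,
                    unit="",
                    dap=tuple(float(d) for d in sub["dap"]),
                    values=tuple(float(v) for v in sub[trait]),
                    level="plant",
                )
            else:
                series = _mean_series(traits, genotype, trait)
            for interval in rgr_table(series):
                rgr_rows.append(
                    {
                        "genotype": genotype,
                        "plant_id": plant_id,
                        "trait": trait,
                        "dap_start": interval.dap_start,
                        "dap_end": interval.dap_end,
                        "rgr": interval.value,
                        "unit": interval.unit,
                    }
                )
            if all(v > 0 for v in series.values):
                fit = fit_compound_interest(series)
                fit_rows.append(
                    {
                        "genotype": genotype,
                        "plant_id": plant_id,
                        "trait": trait,
                        "w0": fit.w0,
                        "r_per_day": fit.r,
                        "n_points": len(series.dap),
                    }
                )
    return pd.DataFrame(rgr_rows), pd.DataFrame(fit_rows)


def validation_report(traits: pd.DataFrame) -> dict:
    """Validation statistics of SPA as a surrogate predictor.

    Per genotype: OLS of each destructive trait on SPA over the time-point
    means; Pearson correlation between interval RGR_BIO and RGR_SPA; and,
    when replicate plants are present, a balanced two-way ANOVA
    (time point × genotype) per trait.
    """
    if "SPA" not in traits.columns:
        raise ValueError("trait table must contain an SPA column")
    responses = [c for c in ("LA", "LDW", "BIO") if c in traits.columns]

    regressions = []
    for genotype in traits["genotype"].unique():
        spa = _mean_series(traits, genotype, "SPA")
        for trait in responses:
            resp = _mean_series(traits, genotype, trait)
            fit = ols_simple(spa.values, resp.values)
            regressions.append(
                {
                    "genotype": genotype,
                    "response": trait,
                    "predictor": "SPA",
                    "slope": fit.slope,
                    "intercept": fit.intercept,
                    "r2": fit.r2,
                    "pearson_r": fit.pearson_r,
                    "n": fit.n,
                    "p_value": fit.p_value,
                }
            )

    correlations = []
    if "BIO" in traits.columns:
        for genotype in traits["genotype"].unique():
            bio_rgr = [iv.value for iv in rgr_table(_mean_series(traits, genotype, "BIO"))]
            spa_rgr = [iv.value for iv in rgr_table(_mean_series(traits, genotype, "SPA"))]
            if len(bio_rgr) >= 3:
                fit = ols_simple(spa_rgr, bio_rgr)
                correlations.append(
                    {
                        "genotype": genotype,
                        "pearson_r": pearson(spa_rgr, bio_rgr),
                        "r2": fit.r2,
                        "n_intervals": len(bio_rgr),
                    }
                )

    anova = {}
    replicated = traits.groupby(["genotype", "dap"]).size().min() > 1
    if replicated and traits["genotype"].nunique() >= 2:
        for trait in [*responses, "SPA"]:
            table = two_way_anova(
                traits.rename(columns={trait: "value"}), value="value"
            )
            anova[trait] = {
                "r2": table.r2,
                "table": table.table.reset_index(names="source"),
            }

    return {
        "regressions": pd.DataFrame(regressions),
        "rgr_correlations": pd.DataFrame(correlations),
        "anova": anova,
    }
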