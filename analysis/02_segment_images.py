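#!/usr/bin/env python
"""Segment the rendered imaging series and check SPA against ground truth.

Runs the full image pipeline (Otsu threshold, binarization, morphological
cleanup, geometry extraction, 12-angle aggregation) over the series from
01_simulate_study.py and compares the recovered per-plant side-projected
area with the renderer's exact foreground truth.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from wheatspa.pipeline import process_image_dir  # noqa: E402
from wheatspa.synthetic import ImagingSpec  # noqa: E402
from wheatspa.traits import Calibration  # noqa: E402

def main() -> int:
    imaging_dir = ROOT / "scratch" / "images"
    if not imaging_dir.exists():
        print("no scratch/images; run analysis/01_simulate_study.py first")
        return 1
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    scale = ImagingSpec().scale
    geometry, aggregated, errors = process_image_dir(imaging_dir, Calibration(scale))
    geometry.to_csv(results / "geometry.csv", index=False)
    aggregated.to_csv(results / "aggregated_spa.csv", index=False)
    print(f"segmented {len(geometry)} views into {len(aggregated)} plant records")
    for err in errors:
        print("error:", err)

    manifest = pd.read_csv(imaging_dir / "manifest.csv")
    truth = manifest.groupby(["plant_id", "dap"])["true_spa_mm2"].mean().rename("true_spa")
    merged = aggregated.merge(truth, on=["plant_id", "dap"])
    merged["rel_err_pct"] = 100 * (merged["SPA"] - merged["true_spa"]).abs() / merged["true_spa"]
    merged.to_csv(results / "spa_recovery.csv", index=False)
    print(f"SPA recovery vs ground truth: mean {merged.rel_err_pct.mean():.2f}%, "
          f"worst {merged.rel_err_pct.max():.2f}% over {len(merged)} plants "
          f"-> results/spa_recovery.csv")
    return 1 if errors else 0


if __name__ == "__main__":
    sys.exit(main())
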