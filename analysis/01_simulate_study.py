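#!/usr/bin/env python
"""Simulate the destructive growth study and render its imaging series.

Generates the synthetic stand-in for the growth-chamber experiment: two
genotypes (an early-heading fast starter and a late-heading tall finisher),
eight sampling dates from 21 to 53 days after planting, independent
replicate plants per date.  The trait table goes to results/; the rendered
side-view images (12 angles per plant) and their ground-truth manifest go
to scratch/images/, where 02_segment_images.py picks them up.

A single replicate per date is rendered to keep the imaging series small;
the trait table keeps the full five replicates.
"""

import sys
from dataclasses import replace
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]

from wheatspa.synthetic import (  # noqa: E402
    DEFAULT_GROWTH_SPEC,
    ImagingSpec,
    simulate_destructive_study,
    simulate_imaging_series,
)

def main() -> int:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    traits = simulate_destructive_study(DEFAULT_GROWTH_SPEC)
    traits.to_csv(results / "synthetic_traits.csv", index=False)
    print(f"trait table: {len(traits)} plants "
          f"({traits.genotype.nunique()} genotypes x {traits.dap.nunique()} dates x "
          f"{DEFAULT_GROWTH_SPEC.replicates} replicates) -> results/synthetic_traits.csv")

    imaging_dir = ROOT / "scratch" / "images"
    render_spec = replace(DEFAULT_GROWTH_SPEC, replicates=1)
    manifest = simulate_imaging_series(render_spec, ImagingSpec(), imaging_dir)
    print(f"imaging series: {len(manifest)} views "
          f"({manifest.plant_id.nunique()} plants x 12 angles) -> scratch/images/")
    return 0


if __name__ == "__main__":
    sys.exit(main())
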