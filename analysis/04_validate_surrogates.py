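#!/usr/bin/env python
"""Validate SPA as a surrogate for the destructive traits.

Per genotype: OLS of leaf area, leaf dry weight and biomass on SPA over
the time-point means; Pearson correlation between interval RGR_BIO and
RGR_SPA; and, on the replicated synthetic study, a balanced two-way ANOVA
(time point × genotype with interaction) per trait.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

from wheatspa.pipeline import validation_report  # noqa: E402
from wheatspa.reference_data import destructive_means_frame  # noqa: E402

def main() -> int:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    ref_report = validation_report(destructive_means_frame())
    ref_report["regressions"].to_csv(results / "regressions_reference.csv", index=False)
    ref_report["rgr_correlations"].to_csv(results / "rgr_correlations_reference.csv", index=False)
    for _, row in ref_report["regressions"].iterrows():
        print(f"{row.genotype:<12} {row.response} = {row.slope:.4f} SPA + {row.intercept:.1f} "
              f"(R2 {100 * row.r2:.1f}%, r {row.pearson_r:.2f})")
    for _, row in ref_report["rgr_correlations"].iterrows():
        print(f"{row.genotype:<12} r(RGR_BIO, RGR_SPA) = {row.pearson_r:.2f} "
              f"(R2 {100 * row.r2:.0f}%)")

    synth_path = results / "synthetic_traits.csv"
    if synth_path.exists():
        syn_report = validation_report(pd.read_csv(synth_path))
        syn_report["regressions"].to_csv(results / "regressions_synthetic.csv", index=False)
        for trait, entry in syn_report["anova"].items():
            entry["table"].to_csv(results / f"anova_{trait}_synthetic.csv", index=False)
            p_int = entry["table"].set_index("source").loc["interaction", "p"]
            print(f"ANOVA {trait}: model R2 {entry['r2']:.3f}, interaction p {p_int:.2g}")
    else:
        print("(no synthetic trait table yet; run 01_simulate_study.py for it)")
    print("-> results/regressions_*.csv, results/anova_*_synthetic.csv")
    return 0


if __name__ == "__main__":
    sys.exit(main())
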