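"""Published reference measurements from the wheat validation study.

Two spring wheat genotypes (Yecora-Rojo and Seri-82) were grown in a
controlled chamber and sampled destructively at eight time points
(21–53 days after planting, DAP), five independent plants per genotype per
time point.  At each time point the study reports per-genotype means (with
standard errors, n = 5) of leaf area (LA, cm²), leaf dry weight (LDW, mg),
above-ground biomass (BIO, mg) and the image-derived side-projected area
(SPA, mm²), together with the derived interval relative growth rates and
the SPA-predictor regression rows.  These printed values are embedded
read-only as the reproduction anchors for the analysis pipeline.
"""

from __future__ import annotations

import pandas as pd

SCHEDULE: tuple[int, ...] = (21, 25, 30, 35, 39, 44, 49, 53)
GENOTYPES: tuple[str, str] = ("Yecora-Rojo", "Seri-82")
TRAITS: tuple[str, ...] = ("LA", "LDW", "BIO", "SPA")

#: Heading dates observed in the study: Yecora-Rojo headed at 39 DAP, Seri-82
#: between the 49 and 53 DAP time points.
HEADING_DAP = {"Yecora-Rojo": 39, "Seri-82": 51}

# Per-genotype trait means over n = 5 destructively sampled plants, one row
# per time point in SCHEDULE order.  LA cm², LDW mg, BIO mg, SPA mm².
DESTRUCTIVE_MEANS = {
    "Yecora-Rojo": {
        "LA": (160, 367, 601, 649, 726, 756, 771, 810),
        "LDW": (720, 1610, 3010, 3630, 4090, 4930, 5280, 5690),
        "BIO": (920, 2290, 5800, 11620, 16220, 26220, 36070, 45390),
        "SPA": (12542, 22359, 38115, 49408, 61093, 76230, 79450, 81479),
    },
    "Seri-82": {
        "LA": (118, 290, 572, 884, 1173, 1594, 1887, 1800),
        "LDW": (550, 1300, 3510, 5000, 7080, 10000, 11240, 11450),
        "BIO": (730, 1800, 5000, 9000, 12000, 19000, 32980, 41600),
        "SPA": (10882, 21795, 37825, 51398, 64438, 77526, 107159, 105419),
    },
}

# Standard errors of the means above (n = 5).
DESTRUCTIVE_SES = {
    "Yecora-Rojo": {
        "LA": (17, 55, 34, 28, 49, 31, 31, 30),
        "LDW": (70, 280, 120, 110, 240, 100, 90, 90),
        "BIO": (90, 460, 460, 390, 980, 740, 1540, 910),
        "SPA": (960, 2463, 2198, 1175, 2732, 2238, 1476, 2137),
    },
    "Seri-82": {
        "LA": (13, 33, 34, 45, 85, 158, 77, 105),
        "LDW": (70, 150, 400, 300, 350, 800, 520, 650),
        "BIO": (100, 200, 400, 500, 190, 1000, 1030, 2310),
        "SPA": (1006, 1752, 1526, 2765, 4029, 4491, 1534, 2887),
    },
}

# Printed interval relative growth rates over the seven consecutive DAP
# intervals (21–25, 25–30, 30–35, 35–39, 39–44, 44–49, 49–53).
# LDW/BIO in mg g-1 d-1, SPA in mm2 mm-2 d-1.
PUBLISHED_RGR = {
    "Yecora-Rojo": {
        "LDW": (309, 173.9, 41.2, 31.7, 41.1, 14.2, 19.4),
        "BIO": (372.3, 306.6, 200.7, 99, 123.3, 75.1, 64.6),
        "SPA": (0.196, 0.141, 0.059, 0.059, 0.05, 0.008, 0.006),
    },
    "Seri-82": {
        "LDW": (345.5, 335.9, 106, 79.6, 76, 29.9, 4.8),
        "BIO": (349.3, 352, 170.2, 90.9, 115.7, 142.8, 65.3),
        "SPA": (0.251, 0.147, 0.072, 0.063, 0.041, 0.054, -0.007),
    },
}

#: Decimal places at which each RGR row is printed (for half-up comparison).
PUBLISHED_RGR_DECIMALS = {"LDW": 1, "BIO": 1, "SPA": 3}

# Printed simple-regression rows, trait ~ SPA on the 8 per-genotype means:
# (slope, intercept, r2_percent, pearson_r).
PUBLISHED_REGRESSIONS = {
    "Yecora-Rojo": {
        "LA": (0.008, 178.85, 88.9, 0.94),
        "LDW": (0.066, 149.1, 98.4, 0.99),
        "BIO": (0.5709, -11956, 85.6, 0.93),
    },
    "Seri-82": {
        "LA": (0.0188, -81.859, 98.0, 0.99),
        "LDW": (0.1187, -782.3, 97.9, 0.99),
        "BIO": (0.3982, -8430.7, 91.2, 0.95),
    },
}

#: Printed Pearson correlations between interval RGR_BIO and RGR_SPA.
PUBLISHED_RGR_CORRELATIONS = {"Yecora-Rojo": 0.97, "Seri-82": 0.91}


def destructive_means_frame() -> pd.DataFrame:
    """Tidy frame of the per-genotype trait means: genotype, dap, LA, LDW, BIO, SPA."""
    rows = []
    for genotype in GENOTYPES:
        for i, dap in enumerate(SCHEDULE):
            rows.append(
                {
                    "genotype": genotype,
                    "dap": dap,
                    **{t: DESTRUCTIVE_MEANS[genotype][t][i] for t in TRAITS},
                }
            )
    return pd.DataFrame(rows)


def trait_series(genotype: str, trait: str):
    """The mean trajectory of one trait as a growth-module TraitSeries."""
    from .growth import TraitSeries

    units = {"LA": "cm2", "LDW": "mg", "BIO": "mg", "SPA": "mm2"}
    return TraitSeries(
        trait=trait,
        unit=units[trait],
        dap=tuple(float(d) for d in SCHEDULE),
        values=tuple(float(v) for v in DESTRUCTIVE_MEANS[genotype][trait]),
        level="genotype-mean",
    )
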