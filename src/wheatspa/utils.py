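"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round half away from zero at ``decimals`` places.

    Published tables round half-up (372.28 → 372.3), unlike Python's
    banker's rounding; comparisons against printed values use this rule.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))
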