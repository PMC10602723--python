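"""Shared numeric helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int) -> float:
    """Round ties away from zero, matching how weight tables and percentages
    are conventionally printed (Python's built-in ``round`` uses banker's
    rounding, which would print 0.00125 as 0.0012)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
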