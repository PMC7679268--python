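"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, decimals: int = 3) -> float:
    """Round to ``decimals`` places with ties going away from zero.

    Python's built-in ``round`` uses banker's rounding; published tables of
    agreement indexes conventionally round half away from zero, and golden
    comparisons follow that convention.
    """
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(x).quantize(quantum, rounding=ROUND_HALF_UP))
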