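"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as in the study's tables.

    Python's built-in ``round`` uses banker's rounding; published clinical
    tables conventionally round halves up (4.005 % -> 4.01 %).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(count: int, total: int, ndigits: int = 2) -> float:
    """Percentage 100*count/total, rounded half-up."""
    if total == 0:
        raise ZeroDivisionError("percentage of an empty total")
    return round_half_up(100.0 * count / total, ndigits)
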