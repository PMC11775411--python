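"""Small shared helpers."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero at the given decimal place.

    Python's built-in ``round`` uses banker's rounding; occurrence counts and
    percentage tables here are reconstructed with conventional half-up
    rounding (e.g. 2.5 -> 3, 24.32 * 37 / 100 = 8.9984 -> 9).
    """
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
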