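"""Half-up decimal rounding used for all displayed scores."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round *x* half away from zero to *decimals* places.

    Python's built-in ``round`` is banker's rounding; published scores use
    conventional half-up (e.g. 0.575 -> 0.58).  The float is taken at its
    shortest round-trip decimal representation (``repr``), so sums of
    decimal grade weights such as 0.375 + 0.2 are treated as the exact
    decimal 0.575 they stand for rather than as the nearest binary double,
    and ties round away from zero.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
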