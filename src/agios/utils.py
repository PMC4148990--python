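"""Small shared helpers: deterministic rounding and percentage arithmetic.

All user-facing percentages in reports follow round-half-up (the convention
under which every reproduced annotation-table cell checks out), never Python's
banker's rounding.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round ``x`` to ``ndigits`` decimals, ties away from zero upward."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator, round-half-up to ``ndigits`` decimals.

    Integer inputs are divided exactly in decimal arithmetic so printed-table
    reproduction does not depend on binary float artifacts.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    value = 100 * Decimal(repr(numerator)) / Decimal(repr(denominator))
    q = Decimal(1).scaleb(-ndigits)
    return float(value.quantize(q, rounding=ROUND_HALF_UP))
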