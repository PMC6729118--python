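"""Half-up decimal rounding used for all reported percentages.

Python's builtin ``round`` is banker's rounding; report tables here follow
the conventional half-up rule (x.x5 rounds away from zero).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round ``value`` to ``ndigits`` decimal places, ties going up.

    Goes through ``Decimal(str(value))`` so that the shortest decimal
    representation of the float, not its binary expansion, is rounded.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(str(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def pct(numerator: float, denominator: float) -> float:
    """Plain percentage, no rounding."""
    return numerator / denominator * 100.0
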