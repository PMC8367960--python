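"""Centralised rounding helpers.

All print-matching in this package goes through these functions so that
half-up rounding (the convention used for reported capacities and counts)
and truncation (used for whole-quintal forage and two-decimal correction
factors) are applied consistently everywhere.
"""

from __future__ import annotations

import math
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal


def round_half_up(value: float, decimals: int = 0) -> float:
    """Round with ties going away from zero, e.g. 0.5 -> 1, 2.675 -> 2.68.

    Python's built-in ``round`` is banker's rounding; field reports use
    arithmetic half-up, so capacities like 435.82 -> 436 and survey means
    print the way a hand calculation would.
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    value = float(value)  # accept numpy scalars
    if not math.isfinite(value):
        return value
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def trunc_decimals(value: float, decimals: int = 0) -> float:
    """Truncate toward zero at ``decimals`` places (0.7258 -> 0.72).

    Implemented on ``Decimal`` so binary-float artefacts such as
    ``0.29 * 100 == 28.999...996`` cannot shift the truncation.
    """
    if decimals < 0:
        raise ValueError("decimals must be >= 0")
    value = float(value)
    if not math.isfinite(value):
        return value
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_DOWN))
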