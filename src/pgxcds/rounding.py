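"""Shared percentage convention: integer percent, half rounded away from zero.

All modules that print a percentage go through :func:`pct` so reports agree
with each other (e.g. 141/251 -> 56, 27/251 -> 11).
"""

from __future__ import annotations

import math


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero (so 2.5 -> 3, -2.5 -> -3)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


def pct(numerator: float, denominator: float) -> int:
    """Integer percentage of ``numerator`` over ``denominator``.

    Raises ZeroDivisionError on a zero denominator; callers guard with their
    own EMPTY_* errors first.
    """
    return round_half_away(100.0 * numerator / denominator)
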