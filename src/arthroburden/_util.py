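"""Small numeric helpers shared across modules."""

from __future__ import annotations

import math

__all__ = ["round_half_away", "iround_half_away"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with halves away from zero (0.5 -> 1, -0.5 -> -1).

    Report-facing deltas and percentages use this convention throughout;
    Python's built-in banker's rounding would map 8061.5 to 8062 but
    82.65 to 82.6.  Values are cleaned at 9 decimals first so that float
    representation noise (e.g. 82.64999999...) does not flip a half.
    """
    scale = 10.0**ndigits
    scaled = round(x * scale, 9)
    if scaled >= 0:
        return math.floor(scaled + 0.5) / scale
    return math.ceil(scaled - 0.5) / scale


def iround_half_away(x: float) -> int:
    """round_half_away to an integer."""
    return int(round_half_away(x, 0))
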