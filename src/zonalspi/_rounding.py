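"""Half-away-from-zero decimal rounding for reported percentages.

Python's built-in round() is banker's rounding (31.25 -> 31.2); the reported
zonal percentages require 31.25 -> 31.3, so rounding goes through Decimal
with ROUND_HALF_UP on the shortest repr of the float.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal


def round_half_away(x: float, ndigits: int = 1) -> float:
    x = float(x)
    if x != x:  # NaN passes through
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))
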