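"""Small shared helpers."""

from __future__ import annotations

import decimal


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, the convention used in clinical reports.

    Python's built-in ``round`` is banker's rounding; stability and clearance
    tables in the field round 0.655 -> 0.66, 11.35 -> 11.4.
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))
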