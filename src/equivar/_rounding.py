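"""Half-up decimal rounding shared by the scoring and frequency layers.

Python's built-in ``round`` is banker's rounding; the tables this package
reproduces were rounded half-up, and frequencies such as 10/202 = 0.0495...
must round to 0.050, not 0.049.
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


def round_half_up(value: float, ndigits: int) -> float:
    """Round *value* to *ndigits* decimals, ties away from zero."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))
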