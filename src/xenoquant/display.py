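"""Display-rounding conventions for the exposure report.

All internal arithmetic is full precision; these helpers only produce the
values a report prints. Convention: quantities below 100 are shown to two
significant figures, larger ones to the nearest integer; dimensionless
ratios below 10 keep two significant figures so small margins stay legible.
"""
from __future__ import annotations

import math


def round_sig(x: float, n: int = 2) -> float:
    """Round ``x`` to ``n`` significant figures (0 stays 0)."""
    if x == 0 or not math.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (n - 1))


def display_value(x: float) -> float:
    """General report value: 2 s.f. below 100, nearest integer above."""
    if abs(x) >= 100:
        return float(round(x))
    return round_sig(x, 2)


def display_ratio(x: float) -> float:
    """Ratio/MoE cell: nearest integer at >=10, else 2 s.f."""
    if abs(x) >= 10:
        return float(round(x))
    return round_sig(x, 2)
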