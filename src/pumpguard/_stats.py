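"""Small shared numeric helpers: percentage rounding and summary statistics."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence


def pct(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage with round-half-up at ``ndigits`` decimals.

    All printed percentages in the package go through this single code path so
    counts and percentages can always be re-derived from each other.
    """
    if denominator == 0:
        raise ZeroDivisionError("percentage undefined for zero denominator")
    q = Decimal(numerator) / Decimal(denominator) * 100
    exp = Decimal(1).scaleb(-ndigits)
    return float(q.quantize(exp, rounding=ROUND_HALF_UP))


def describe(values: Sequence[float]) -> dict[str, Optional[float]]:
    """Mean, sample SD (ddof=1), median, min, max, n; None-safe for n<2."""
    vals = sorted(float(v) for v in values)
    n = len(vals)
    if n == 0:
        return {"n": 0, "mean": None, "sd": None, "median": None, "min": None, "max": None}
    mean = sum(vals) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1)) if n > 1 else None
    mid = n // 2
    median = vals[mid] if n % 2 else (vals[mid - 1] + vals[mid]) / 2
    return {
        "n": n,
        "mean": mean,
        "sd": sd,
        "median": median,
        "min": vals[0],
        "max": vals[-1],
    }
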