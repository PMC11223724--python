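"""Small numeric helpers shared across modules."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round ``x`` to ``ndigits`` decimals, halves away from zero.

    Python's built-in :func:`round` uses banker's rounding; printed clinical
    tables round halves away from zero (14.035 -> 14.04), so reported rates,
    ratios and integer extrapolations go through this helper instead.
    """
    if not np.isfinite(x):
        return float(x)
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_half_away_vec(x, ndigits: int = 0) -> np.ndarray:
    return np.array([round_half_away(float(v), ndigits) for v in np.atleast_1d(x)])


def percentage(k: float, n: float, ndigits: int = 2) -> float:
    """Share of ``k`` in ``n`` as a percentage, rounded for reporting."""
    if n == 0:
        return float("nan")
    return round_half_away(100.0 * k / n, ndigits)


def per_case_rate(total: float, n_cases: int, ndigits: int = 2) -> float:
    """Annotations per case, rounded to the table precision (2 decimals)."""
    if n_cases == 0:
        return float("nan")
    return round_half_away(total / n_cases, ndigits)
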