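"""Small shared helpers: half-up percentage rounding, Welch test with a
degenerate-variance rule."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import stats


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of hand-formatted tables),
    unlike Python's banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def pct(numer: float, denom: float, ndigits: int = 2) -> float:
    return round_half_up(100.0 * numer / denom, ndigits)


def ttest_p(a, b, equal_var: bool = False) -> float:
    """Two-sided two-sample t p-value with a degenerate-variance rule.

    If both samples are constant the t statistic is undefined; the rule is
    p = 1 when the constants agree (no evidence of difference) and p = 0
    when they differ (difference certain under zero observed noise).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        return 1.0 if a[0] == b[0] else 0.0
    return float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)


def welch_p(a, b) -> float:
    """Two-sided Welch (unequal-variance) t p-value with the
    degenerate-variance rule; appropriate for unequal group sizes."""
    return ttest_p(a, b, equal_var=False)
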