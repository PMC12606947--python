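"""Exact tests used by the positional map modules.

The two-tailed Fisher / hypergeometric p-value is computed with integer
arithmetic (math.comb), summing all tables with the observed margins whose
point probability is <= the observed table's. The comparison between
candidate tables is done on exact integer numerators, so boundary ties are
handled without floating-point tolerance.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy import stats as _scipy_stats


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed exact p for the 2x2 table [[a, b], [c, d]].

    Two-sided convention: sum of hypergeometric outcomes with point
    probability <= that of the observed table (the usual "small-p" rule).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    n = a + b + c + d
    if n == 0:
        return float("nan")
    r1 = a + b
    c1 = a + c
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    obs = comb(r1, a) * comb(n - r1, c1 - a)
    numer = 0
    for k in range(lo, hi + 1):
        term = comb(r1, k) * comb(n - r1, c1 - k)
        if term <= obs:
            numer += term
    return numer / comb(n, c1)


# the hypergeometric test on a 2x2 layout is the same exact computation;
# exposed under its own name because the motif modules refer to it as such
hypergeom_two_tailed = fisher_exact_two_tailed


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample two-tailed Kolmogorov-Smirnov test.

    Exact null distribution when the smaller group has <= 10 observations,
    asymptotic otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if min(x.size, y.size) <= 10 else "asymp"
    res = _scipy_stats.ks_2samp(x, y, method=method)
    return float(res.statistic), float(res.pvalue)


def neg_log10(p: float) -> float:
    if np.isnan(p):
        return float("nan")
    return float(-np.log10(max(p, 1e-300)))
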