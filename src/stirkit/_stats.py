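"""Shared statistical primitives: paired signed-rank test, proportion test,
Bonferroni correction.

The paired comparison used throughout (region vs its aggregated control
quintet) is the Wilcoxon signed-rank test on paired differences, exact for
small samples, with zero differences dropped.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def paired_signed_rank(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are dropped; if every difference is zero the test is
    degenerate and p = 1.  scipy uses the exact null distribution for small
    n and the normal approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    d = x[mask] - y[mask]
    d = d[d != 0]
    if d.size == 0:
        return 1.0
    res = stats.wilcoxon(d, zero_method="wilcox", correction=True, mode="auto")
    return float(res.pvalue)


def proportion_test(k1: int, n1: int, k2: int, n2: int) -> float:
    """Two-sided test for equality of two proportions with continuity
    correction (chi-square on the 2x2 table, Yates-corrected; equivalent to
    R's prop.test)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(p)


def bonferroni(p, m: int):
    """Bonferroni-correct p-value(s) over a family of size m, capped at 1."""
    return np.minimum(np.asarray(p, dtype=float) * m, 1.0)
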