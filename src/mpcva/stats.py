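"""Statistical comparisons used by both assay arms.

The time-lapse arm compares viable-labeled against dead-labeled
intensity values with the Mann-Whitney U test (chosen because dead-cell
intensities deviate both above and below the viable values, so a
rank-based two-sided test captures both tails).  The cytometry arm
compares 2x2 viable/dead count tables — treated vs control, or the two
1 h duplicates of one sample — with Pearson's Chi-squared test.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = ["mann_whitney", "chi_squared", "EXACT_MAX_TOTAL"]

#: Largest pooled sample size for which the exact (enumeration) p is used.
EXACT_MAX_TOTAL = 14


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U of the first sample, with tie handling via midranks."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(a)].sum()
    return float(r1 - len(a) * (len(a) + 1) / 2.0)


def _exact_two_sided_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Exact two-sided p by full enumeration of group labelings.

    Enumerates all C(n+m, n) assignments of the pooled values to the two
    groups and counts those whose U deviates from the null mean n*m/2 at
    least as much as the observed U.  Valid with ties (midranks are
    recomputed per labeling implicitly through the pooled ranking).
    """
    pooled = np.concatenate([a, b])
    n, m = len(a), len(b)
    ranks = sps.rankdata(pooled)
    center = n * m / 2.0
    dev_obs = abs(u_obs - center) - 1e-12
    hits = 0
    for idx in combinations(range(n + m), n):
        r1 = ranks[list(idx)].sum()
        u = r1 - n * (n + 1) / 2.0
        if abs(u - center) >= dev_obs:
            hits += 1
    return hits / comb(n + m, n)


def mann_whitney(a, b) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Returns ``(U, p)`` where U is the statistic of the first sample.
    For small pooled samples (n + m <= 14) the p-value is exact, by full
    enumeration of the C(n+m, n) group labelings (which remains valid in
    the presence of ties); larger samples use the normal approximation
    with the midrank tie correction.  If every value in both samples is
    identical the test is uninformative and p = 1 is returned with a
    warning.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    if np.ptp(np.concatenate([a, b])) == 0:
        warnings.warn(
            "all values identical across both samples; p-value set to 1",
            RuntimeWarning,
            stacklevel=2,
        )
        return u, 1.0
    if len(a) + len(b) <= EXACT_MAX_TOTAL:
        return u, _exact_two_sided_p(a, b, u)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u, float(min(res.pvalue, 1.0))


def chi_squared(table) -> tuple[float, float]:
    """Pearson Chi-squared test on a 2x2 count table, 1 df, no continuity
    correction.

    Raises on degenerate tables (a zero row or column makes an expected
    count zero and the statistic undefined).
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("degenerate table: zero row or column total")
    res = sps.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)
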