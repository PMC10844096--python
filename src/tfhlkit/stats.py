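"""Shared statistical primitives: the Wilcoxon rank-sum engine used by all
group comparisons, the signed-rank wrapper, and multiple-testing corrections.

The rank-sum test is exact (full permutation distribution of the rank sum,
tie-aware) when both groups have at most ``exact_max_n`` observations, and a
normal approximation with tie correction and continuity correction otherwise.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = ["rank_sum_test", "signed_rank_test", "adjust_pvalues"]


def _exact_rank_sum_p(ranks2: np.ndarray, n: int, w_obs2: int) -> float:
    """Exact two-sided p for the rank-sum statistic with tie-averaged ranks.

    ``ranks2`` are pooled average ranks doubled to integers; ``w_obs2`` is the
    doubled observed rank sum of the size-``n`` group. Counts subsets of size
    n by dynamic programming over (subset size, doubled rank sum) and returns
    P(|W - E[W]| >= |W_obs - E[W]|) under uniform subset choice.
    """
    total = int(ranks2.sum())
    # dp[k] maps doubled-sum -> number of size-k subsets achieving it
    max_sum = total
    dp = np.zeros((n + 1, max_sum + 1), dtype=np.float64)
    dp[0, 0] = 1.0
    for r in ranks2:
        upper = min(n, len(ranks2))
        for k in range(upper - 1, -1, -1):
            row = dp[k]
            nz = np.nonzero(row)[0]
            if nz.size:
                dp[k + 1, nz + r] += row[nz]
    counts = dp[n]
    sums = np.arange(max_sum + 1)
    # E[2W] = n * mean(ranks2); with full-integer arithmetic via Fractions
    e2w = Fraction(n * total, len(ranks2))
    dev_obs = abs(Fraction(w_obs2) - e2w)
    devs = np.abs(sums - float(e2w))
    # tolerate float fuzz at the boundary
    extreme = devs >= float(dev_obs) - 1e-9
    return float(counts[extreme].sum() / counts.sum())


def rank_sum_test(x, y, exact_max_n: int = 10) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Returns ``(rank_sum_of_x, p_two_sided)``. Exact enumeration of the
    permutation null (tie-aware) when both groups have <= ``exact_max_n``
    observations; otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    w = float(ranks[: x.size].sum())
    if x.size <= exact_max_n and y.size <= exact_max_n:
        ranks2 = np.round(ranks * 2).astype(int)
        w2 = int(round(w * 2))
        p = _exact_rank_sum_p(ranks2, x.size, w2)
    else:
        _, p = scipy.stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(p)
    return w, min(p, 1.0)


def signed_rank_test(values, center: float = 0.0) -> float:
    """Two-sided one-sample Wilcoxon signed-rank p-value of values vs center.

    Zero differences are dropped (Wilcoxon's convention); all-zero input
    returns p = 1.
    """
    diffs = np.asarray(values, dtype=float) - center
    diffs = diffs[diffs != 0]
    if diffs.size == 0:
        return 1.0
    res = scipy.stats.wilcoxon(diffs, alternative="two-sided")
    return float(res.pvalue)


def adjust_pvalues(pvalues, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing correction; method in {'bonferroni', 'BH'}."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if method == "bonferroni":
        return np.minimum(p * p.size, 1.0)
    if method == "BH":
        return multipletests(p, method="fdr_bh")[1]
    raise ValueError(f"unknown correction method: {method!r}")
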