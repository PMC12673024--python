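"""Nonparametric statistics with exact small-sample p-values.

Wilcoxon matched-pairs signed-rank for paired data, Mann-Whitney for
two independent samples, Spearman rank correlation — the toolkit used
to compare pre/post time points, sexes, and parameter associations.
All tests are two-sided.  Exact p-values are computed by complete
enumeration when the sample is small enough (sign assignments for the
signed-rank test, label assignments for Mann-Whitney, permutations for
Spearman); otherwise the normal / t approximation is used and flagged.
Ties are handled with mid-ranks; zero differences are dropped
(degenerate all-zero input yields p = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy import stats as sps

__all__ = ["StatResult", "wilcoxon_signed_rank", "mann_whitney", "spearman"]

_EXACT_SIGNRANK_N = 25
_EXACT_PERM_N = 8


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    method: str
    exact: bool
    n: int
    degenerate: bool = False


def _midranks(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def wilcoxon_signed_rank(x, y=None) -> StatResult:
    """Wilcoxon matched-pairs signed-rank test on x - y (or on x alone)."""
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    if d.size < 3:
        raise ValueError("need at least 3 pairs")
    n_total = d.size
    d = d[d != 0.0]
    m = d.size
    if m == 0:
        return StatResult(0.0, 1.0, "wilcoxon-signed-rank", True, n_total,
                          degenerate=True)
    ranks = _midranks(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    if m <= _EXACT_SIGNRANK_N:
        # enumerate all 2^m sign assignments of the ranks
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        lo = np.mean(totals <= w_pos + 1e-12)
        hi = np.mean(totals >= w_pos - 1e-12)
        p = min(1.0, 2.0 * min(lo, hi))
        return StatResult(w_pos, float(p), "wilcoxon-signed-rank", True,
                          n_total)
    mu = m * (m + 1) / 4.0
    sigma = np.sqrt(m * (m + 1) * (2 * m + 1) / 24.0)
    z = (w_pos - mu) / sigma
    p = 2.0 * sps.norm.sf(abs(z))
    return StatResult(w_pos, float(min(1.0, p)), "wilcoxon-signed-rank",
                      False, n_total)


def mann_whitney(x, y) -> StatResult:
    """Mann-Whitney U test for two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if min(n1, n2) < 3:
        raise ValueError("need at least 3 observations per group")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    if max(n1, n2) <= _EXACT_PERM_N:
        idx_all = range(n1 + n2)
        stats_all = []
        for comb in combinations(idx_all, n1):
            r = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2.0
            stats_all.append(r)
        stats_all = np.array(stats_all)
        lo = np.mean(stats_all <= u1 + 1e-12)
        hi = np.mean(stats_all >= u1 - 1e-12)
        p = min(1.0, 2.0 * min(lo, hi))
        return StatResult(u1, float(p), "mann-whitney", True, n1 + n2)
    mu = n1 * n2 / 2.0
    # tie-corrected normal approximation
    _, cnt = np.unique(pooled, return_counts=True)
    tie = (cnt ** 3 - cnt).sum()
    nn = n1 + n2
    sigma = np.sqrt(n1 * n2 / 12.0 * (nn + 1 - tie / (nn * (nn - 1))))
    if sigma == 0:
        return StatResult(u1, 1.0, "mann-whitney", False, nn, degenerate=True)
    z = (u1 - mu) / sigma
    p = 2.0 * sps.norm.sf(abs(z))
    return StatResult(u1, float(min(1.0, p)), "mann-whitney", False, nn)


def _spearman_r(rx: np.ndarray, ry: np.ndarray) -> float:
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((rx * ry).sum() / denom)


def spearman(x, y) -> StatResult:
    """Spearman rank correlation with exact permutation p for small n."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx, ry = _midranks(x), _midranks(y)
    r = _spearman_r(rx, ry)
    if np.isnan(r):
        return StatResult(float("nan"), 1.0, "spearman", True, n,
                          degenerate=True)
    if n <= _EXACT_PERM_N:
        count = 0
        total = 0
        for perm in permutations(ry):
            rp = _spearman_r(rx, np.array(perm))
            if abs(rp) >= abs(r) - 1e-12:
                count += 1
            total += 1
        return StatResult(r, count / total, "spearman", True, n)
    # t approximation
    t = r * np.sqrt((n - 2) / max(1e-15, 1.0 - r * r))
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return StatResult(r, float(min(1.0, p)), "spearman", False, n)
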