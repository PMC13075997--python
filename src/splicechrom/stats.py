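"""Statistical primitives: rank-sum test, multiple-testing corrections,
correlations.

The Mann-Whitney U test is implemented with an exact small-sample mode
(full enumeration of the null U distribution via the standard partition
recursion) and a large-sample normal approximation with tie and continuity
corrections, matching R's ``wilcox.test`` conventions. ``auto`` mode uses
exact enumeration whenever both samples have at most ``exact_limit``
observations and no ties are present — the regime where the normal
approximation is measurably inaccurate — and the corrected approximation
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    method: str
    n1: int
    n2: int


EXACT_LIMIT = 8


@lru_cache(maxsize=64)
def _u_null_counts(n: int, m: int) -> tuple[int, ...]:
    """Number of rank arrangements yielding each U value, U in 0..n*m.

    Classic recursion c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u) counting
    partitions of u into at most n parts each at most m.
    """
    top = n * m
    # prev[j][u] = c(i-1, j, u); recurrence c(i, j, u) = c(i-1, j, u-j) + c(i, j-1, u)
    prev = [[1 if u == 0 else 0 for u in range(top + 1)] for _ in range(m + 1)]
    for _i in range(1, n + 1):
        cur = [[0] * (top + 1) for _ in range(m + 1)]
        cur[0][0] = 1
        for j in range(1, m + 1):
            row = cur[j]
            below = cur[j - 1]
            shifted = prev[j]
            for u in range(top + 1):
                row[u] = below[u] + (shifted[u - j] if u >= j else 0)
        prev = cur
    return tuple(prev[m])


def _mw_u(x: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u = ranks[: len(x)].sum() - len(x) * (len(x) + 1) / 2.0
    return float(u), ranks


def _exact_two_sided_p(u: float, n: int, m: int) -> float:
    counts = np.array(_u_null_counts(n, m), dtype=np.float64)
    total = counts.sum()
    center = n * m / 2.0
    dev = abs(u - center)
    extreme = counts[np.abs(np.arange(n * m + 1) - center) >= dev - 1e-9].sum()
    return min(1.0, float(extreme / total))


def _approx_two_sided_p(u: float, n: int, m: int, ranks: np.ndarray) -> float:
    N = n + m
    mu = n * m / 2.0
    _, cnt = np.unique(ranks, return_counts=True)
    tie_term = float(((cnt**3) - cnt).sum())
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 1.0
    z = (abs(u - mu) - 0.5) / np.sqrt(var)  # continuity correction
    z = max(z, 0.0)
    return float(min(1.0, 2.0 * sps.norm.sf(z)))


def mann_whitney(x, y, mode: str = "auto") -> TestResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test.

    mode: ``exact`` (full enumeration; requires no ties), ``normal-approx``
    (tie- and continuity-corrected normal approximation), or ``auto``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n, m = len(x), len(y)
    u, ranks = _mw_u(x, y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n + m
    if mode == "auto":
        mode = "exact" if (n <= EXACT_LIMIT and m <= EXACT_LIMIT and not has_ties) else "normal-approx"
    if mode == "exact":
        if has_ties:
            raise ValueError("exact mode requires tie-free data")
        p = _exact_two_sided_p(u, n, m)
        method = "mann-whitney-exact"
    elif mode == "normal-approx":
        p = _approx_two_sided_p(u, n, m, ranks)
        method = "mann-whitney-normal-approx"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(statistic=u, pvalue=p, method=method, n1=n, n2=m)


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """min(1, p * m); m defaults to the number of p-values."""
    p = np.asarray(pvals, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    return np.minimum(1.0, p * m)


def benjamini_hochberg(pvals) -> np.ndarray:
    """BH step-up adjusted p-values with monotonicity enforcement."""
    p = np.asarray(pvals, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def correlation(x, y, method: str = "pearson") -> float:
    """Pearson product-moment or Spearman rank correlation coefficient."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("samples must have equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance sample: correlation undefined")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")
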