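"""Wilcoxon/Mann-Whitney rank-sum machinery shared by the gene filters.

Two evaluation routes are provided:

* an exact route that enumerates the permutation null of the rank sum with a
  subset-sum dynamic program over (doubled) midranks, valid with ties; for
  untied data the null depends only on the group sizes and is cached;
* a normal approximation with midrank tie correction and continuity
  correction, used for larger designs.

The statistic reported is the Mann-Whitney U of the first sample
(``U = W_x - n(n+1)/2``); ``alternative="greater"`` means the first sample is
stochastically larger.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np
from scipy import stats

__all__ = ["rank_sum_test", "rank_sum_test_matrix"]

#: exact enumeration is used (method="auto") up to this pooled size
EXACT_MAX_TOTAL = 40

_ALTERNATIVES = ("greater", "less", "two-sided")


def _check_alternative(alternative: str) -> None:
    if alternative not in _ALTERNATIVES:
        raise ValueError(f"alternative must be one of {_ALTERNATIVES}")


def _rank_sum_counts(midranks2: np.ndarray, n: int) -> np.ndarray:
    """Count subsets of size ``n`` by their doubled-rank sum.

    Returns an array ``c`` with ``c[s]`` = number of size-``n`` subsets of the
    pooled doubled midranks summing to ``s``.
    """
    total = int(midranks2.sum())
    f = np.zeros((n + 1, total + 1))
    f[0, 0] = 1.0
    for r in midranks2:
        r = int(r)
        for k in range(n, 0, -1):
            f[k, r:] += f[k - 1, : total + 1 - r]
    return f[n]


@lru_cache(maxsize=64)
def _untied_null_sf(n: int, m: int) -> np.ndarray:
    """Exact survival function of the doubled rank sum for untied data.

    ``sf[s] = P(2*W_x >= s)`` where ranks are 1..n+m without ties.
    """
    ranks2 = 2 * np.arange(1, n + m + 1)
    counts = _rank_sum_counts(ranks2, n)
    counts = counts / math.comb(n + m, n)
    return counts[::-1].cumsum()[::-1]


def _exact_pvalues(midranks2: np.ndarray, n: int, w2: float):
    """One-sided and two-sided exact p for observed doubled rank sum ``w2``."""
    counts = _rank_sum_counts(midranks2, n)
    counts = counts / math.comb(len(midranks2), n)
    sf = counts[::-1].cumsum()[::-1]
    cdf = counts.cumsum()
    s = int(round(w2))
    p_greater = float(sf[s]) if s < len(sf) else 0.0
    p_less = float(cdf[s]) if s < len(cdf) else 1.0
    return p_greater, p_less


def _tie_term(values: np.ndarray) -> float:
    """Sum of t^3 - t over groups of tied values."""
    _, counts = np.unique(values, return_counts=True)
    counts = counts[counts > 1]
    return float((counts**3 - counts).sum())


def _normal_pvalues(w: float, n: int, m: int, tie_term: float):
    N = n + m
    mean = n * (N + 1) / 2.0
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:  # all values identical
        return 1.0, 1.0, 1.0
    sd = math.sqrt(var)
    z_greater = (w - mean - 0.5) / sd
    z_less = (w - mean + 0.5) / sd
    p_greater = float(stats.norm.sf(z_greater))
    p_less = float(stats.norm.cdf(z_less))
    z_abs = max(abs(w - mean) - 0.5, 0.0) / sd
    p_two = min(1.0, 2.0 * float(stats.norm.sf(z_abs)))
    return p_greater, p_less, p_two


def _choose_method(method: str, total: int) -> str:
    if method == "auto":
        return "exact" if total <= EXACT_MAX_TOTAL else "normal"
    if method not in ("exact", "normal"):
        raise ValueError(f"method must be 'auto', 'exact' or 'normal', got {method!r}")
    return method


def rank_sum_test(x, y, *, alternative: str = "two-sided",
                  method: str = "auto") -> tuple[float, float]:
    """Rank-sum test of two independent samples.

    Returns ``(U, p)`` where U is the Mann-Whitney statistic of ``x``.
    """
    _check_alternative(alternative)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 2 or m < 2:
        raise ValueError(f"need >=2 values per sample, got {n} and {m}")
    mode = _choose_method(method, n + m)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n].sum())
    u = w - n * (n + 1) / 2.0

    if mode == "exact":
        midranks2 = np.rint(2 * ranks).astype(int)
        has_ties = len(np.unique(pooled)) < n + m
        if has_ties:
            p_greater, p_less = _exact_pvalues(midranks2, n, 2 * w)
        else:
            sf = _untied_null_sf(n, m)
            s = int(round(2 * w))
            p_greater = float(sf[s])
            # P(W <= w) by symmetry of the untied null around n(N+1)/2
            s_reflect = int(round(2 * (n * (n + m + 1)) - 2 * w))
            p_less = float(sf[s_reflect])
        p_two = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        p_greater, p_less, p_two = _normal_pvalues(w, n, m, _tie_term(pooled))

    if alternative == "greater":
        return u, p_greater
    if alternative == "less":
        return u, p_less
    return u, p_two


def rank_sum_test_matrix(X, Y, *, alternative: str = "two-sided",
                         method: str = "auto") -> tuple[np.ndarray, np.ndarray]:
    """Row-wise rank-sum tests for gene-by-sample matrices.

    ``X`` (genes x n) and ``Y`` (genes x m) hold per-gene samples; returns
    per-gene ``(U, p)`` arrays.  Rows without ties share a single exact null
    distribution; rows with ties fall back to a per-row dynamic program (exact
    mode) or the tie-corrected normal approximation.
    """
    _check_alternative(alternative)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, m = X.shape[1], Y.shape[1]
    if n < 2 or m < 2:
        raise ValueError(f"need >=2 columns per side, got {n} and {m}")
    mode = _choose_method(method, n + m)
    pooled = np.concatenate([X, Y], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    w = ranks[:, :n].sum(axis=1)
    u = w - n * (n + 1) / 2.0
    tied = (np.diff(np.sort(pooled, axis=1), axis=1) == 0).any(axis=1)

    n_rows = pooled.shape[0]
    p_greater = np.empty(n_rows)
    p_less = np.empty(n_rows)
    p_two = np.empty(n_rows)

    if mode == "exact":
        sf = _untied_null_sf(n, m)
        s = np.rint(2 * w).astype(int)
        s_reflect = np.rint(2 * n * (n + m + 1) - 2 * w).astype(int)
        free = ~tied
        p_greater[free] = sf[s[free]]
        p_less[free] = sf[s_reflect[free]]
        for i in np.flatnonzero(tied):
            midranks2 = np.rint(2 * ranks[i]).astype(int)
            p_greater[i], p_less[i] = _exact_pvalues(midranks2, n, 2 * w[i])
        p_two = np.minimum(1.0, 2.0 * np.minimum(p_greater, p_less))
    else:
        N = n + m
        mean = n * (N + 1) / 2.0
        tie_terms = np.zeros(n_rows)
        for i in np.flatnonzero(tied):
            tie_terms[i] = _tie_term(pooled[i])
        var = n * m / 12.0 * ((N + 1) - tie_terms / (N * (N - 1)))
        degenerate = var <= 0
        sd = np.sqrt(np.where(degenerate, 1.0, var))
        p_greater = stats.norm.sf((w - mean - 0.5) / sd)
        p_less = stats.norm.cdf((w - mean + 0.5) / sd)
        p_two = np.minimum(
            1.0, 2.0 * stats.norm.sf(np.maximum(np.abs(w - mean) - 0.5, 0.0) / sd)
        )
        for arr in (p_greater, p_less, p_two):
            arr[degenerate] = 1.0

    if alternative == "greater":
        return u, p_greater
    if alternative == "less":
        return u, p_less
    return u, p_two
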