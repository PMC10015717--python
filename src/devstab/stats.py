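"""Nonparametric inference: Spearman correlation, Kruskal-Wallis, Steel-Dwass.

The Steel-Dwass all-pairs procedure is the rank-based analogue of Tukey's
HSD: for each unordered pair of groups only the two groups are pooled and
midranked, the Mann-Whitney statistic is standardised with the tie-corrected
variance, and ``sqrt(2) * |z|`` is referred to the studentized-range
distribution with k groups and infinite degrees of freedom.  This controls
the familywise error over all k(k-1)/2 comparisons without a separate
multiplicity adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "GroupComparisonResult",
    "spearman_test",
    "kruskal_wallis",
    "steel_dwass",
    "compare_groups",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.rho <= 1.0 + 1e-12:
            raise ValueError(f"|rho| > 1: {self.rho}")


@dataclass(frozen=True)
class GroupComparisonResult:
    """Kruskal-Wallis omnibus plus Steel-Dwass all-pairs comparisons."""

    omnibus_statistic: float
    omnibus_p: float
    pairwise: list[tuple[str, str, float, float]]  # (a, b, z, p)


def spearman_test(x, y, *, method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with a test of no correlation.

    ``method="t"`` (default) uses the t approximation with n-2 degrees of
    freedom, appropriate for the gene-scale n used here.  ``method="exact"``
    enumerates all permutations of one margin (n <= 10) and is intended for
    oracle checks at tiny n.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if method == "t":
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = 2.0 * float(sps.t.sf(abs(t), n - 2))
    elif method == "exact":
        if n > 10:
            raise ValueError("exact mode supports n <= 10")
        rx_c = rx - rx.mean()
        ry_c = ry - ry.mean()
        # |rho| is monotone in |centred rank dot product|, so enumerate that
        obs = abs(float(rx_c @ ry_c))
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            s = abs(float(rx_c @ ry_c[list(perm)]))
            hits += s >= obs - 1e-12
            total += 1
        p = hits / total
    else:
        raise ValueError(f"method must be 't' or 'exact', got {method!r}")
    return CorrelationResult(rho=rho, p_value=min(1.0, p), n=n)


def _as_groups(groups) -> list[np.ndarray]:
    arrays = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrays) < 2:
        raise ValueError(f"need >=2 groups, got {len(arrays)}")
    if any(len(g) == 0 for g in arrays):
        raise ValueError("empty group")
    return arrays


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value."""
    arrays = _as_groups(groups)
    if sum(len(g) for g in arrays) < 3:
        raise ValueError("need total n >= 3")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return 0.0, 1.0
    h, p = sps.kruskal(*arrays)
    return float(h), float(p)


def _pair_z(a: np.ndarray, b: np.ndarray) -> float:
    """Tie-corrected standardised Mann-Whitney z for one group pair."""
    n, m = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = ranks[:n].sum()
    N = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
    if var <= 0:
        return 0.0
    return float((w - n * (N + 1) / 2.0) / math.sqrt(var))


def _permutation_max_z(arrays: list[np.ndarray], n_resamples: int,
                       seed: int) -> np.ndarray:
    """Null distribution of the maximum pairwise |z| under full relabeling."""
    rng = np.random.default_rng(seed)
    sizes = [len(a) for a in arrays]
    bounds = np.cumsum([0] + sizes)
    pooled = np.concatenate(arrays)
    perms = rng.permuted(
        np.tile(np.arange(pooled.size), (n_resamples, 1)), axis=1
    )
    values = pooled[perms]
    max_z = np.zeros(n_resamples)
    for ia, ib in itertools.combinations(range(len(arrays)), 2):
        sub = np.concatenate(
            [values[:, bounds[ia]:bounds[ia + 1]],
             values[:, bounds[ib]:bounds[ib + 1]]], axis=1
        )
        ranks = sps.rankdata(sub, axis=1)
        n, m = sizes[ia], sizes[ib]
        N = n + m
        w = ranks[:, :n].sum(axis=1)
        # tie-corrected variance per resample
        sub_sorted = np.sort(sub, axis=1)
        tie_term = np.zeros(n_resamples)
        has_tie = (np.diff(sub_sorted, axis=1) == 0).any(axis=1)
        for i in np.flatnonzero(has_tie):
            _, counts = np.unique(sub[i], return_counts=True)
            tie_term[i] = float((counts**3 - counts).sum())
        var = n * m / 12.0 * ((N + 1) - tie_term / (N * (N - 1)))
        var[var <= 0] = np.inf
        max_z = np.maximum(max_z, np.abs(w - n * (N + 1) / 2.0) / np.sqrt(var))
    return max_z


def steel_dwass(groups, labels=None, *, method: str = "asymptotic",
                n_resamples: int = 20_000,
                seed: int = 0) -> list[tuple[str, str, float, float]]:
    """Steel-Dwass all-pairs comparisons.

    For each unordered pair of groups, only that pair is pooled and
    midranked and the Mann-Whitney statistic standardised with the
    tie-corrected variance.  With ``method="asymptotic"`` (the usual
    large-sample form) the familywise-adjusted p-value is
    ``P(Q_{k,inf} >= sqrt(2) * |z|)`` with k the total number of groups;
    ``method="permutation"`` refers |z| to the seeded Monte-Carlo null of
    the maximum pairwise |z| under full relabeling, which is more accurate
    for small groups.  Returns ``(label_a, label_b, z, p)`` for every pair.
    """
    arrays = _as_groups(groups)
    if any(len(g) < 2 for g in arrays):
        sizes = [len(g) for g in arrays]
        raise ValueError(f"every group needs >=2 values, got sizes {sizes}")
    k = len(arrays)
    if labels is None:
        labels = [f"group{i}" for i in range(k)]
    if len(labels) != k:
        raise ValueError("labels length must match number of groups")
    if method not in ("asymptotic", "permutation"):
        raise ValueError(f"method must be 'asymptotic' or 'permutation', got {method!r}")
    null_max_z = None
    if method == "permutation":
        null_max_z = _permutation_max_z(arrays, n_resamples, seed)
    out = []
    for ia, ib in itertools.combinations(range(k), 2):
        z = _pair_z(arrays[ia], arrays[ib])
        if null_max_z is not None:
            p = float((null_max_z >= abs(z) - 1e-12).mean())
        else:
            p = float(sps.studentized_range.sf(math.sqrt(2.0) * abs(z), k, np.inf))
        out.append((str(labels[ia]), str(labels[ib]), z, min(1.0, max(p, 0.0))))
    return out


def compare_groups(groups, labels=None) -> GroupComparisonResult:
    """Kruskal-Wallis omnibus followed by Steel-Dwass all-pairs comparisons."""
    h, p = kruskal_wallis(groups)
    pairwise = steel_dwass(groups, labels)
    return GroupComparisonResult(omnibus_statistic=h, omnibus_p=p, pairwise=pairwise)
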