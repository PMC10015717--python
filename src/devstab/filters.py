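"""Gene-selection filters.

Two rank-based filters restrict the analysis to informative genes:

* the technical-error filter keeps genes whose expression differences between
  sibling embryos are significantly greater (one-sided rank-sum, alpha=0.01)
  than the differences between technical replicates — i.e. genes whose
  biological deviation rises above the measurement floor;
* the differential-mean filter compares each gene's per-individual expression
  between two populations with a two-sided rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._ranksum import rank_sum_test_matrix
from .pairing import PairSet
from .preprocess import ExpressionMatrix

__all__ = [
    "pair_differences",
    "technical_error_values",
    "technical_error_filter",
    "differential_mean_filter",
]


def pair_differences(m: ExpressionMatrix, pairs: PairSet) -> pd.DataFrame:
    """Per-gene absolute expression differences ``|x_j^i - x_j^k|``.

    Returns a genes x pairs DataFrame (columns ``"a|b"``) on the log scale.
    """
    if m.units != "log10":
        raise ValueError("pair_differences expects log10-scale values")
    if len(pairs) == 0:
        raise ValueError("empty PairSet")
    missing = [s for s in pairs.sample_ids() if s not in m.data.columns]
    if missing:
        raise ValueError(f"pair members missing from matrix: {missing[:5]}")
    cols_a = [a for a, _ in pairs.pairs]
    cols_b = [b for _, b in pairs.pairs]
    diffs = np.abs(m.data[cols_a].to_numpy() - m.data[cols_b].to_numpy())
    names = [f"{a}|{b}" for a, b in pairs.pairs]
    return pd.DataFrame(diffs, index=m.data.index, columns=names)


def technical_error_values(m: ExpressionMatrix, tech_pairs: PairSet,
                           meta=None, *, mode: str = "pairwise") -> pd.DataFrame:
    """Technical-error samples per gene.

    ``mode="pairwise"`` (default) returns the raw replicate-pair differences
    (six values per condition for four replicates).  ``mode="averaged"``
    returns, per replicate condition, the mean of its pairwise differences;
    this collapses each condition to one error value and requires at least
    two replicated conditions to be testable.
    """
    diffs = pair_differences(m, tech_pairs)
    if mode == "pairwise":
        return diffs
    if mode != "averaged":
        raise ValueError(f"mode must be 'pairwise' or 'averaged', got {mode!r}")
    if meta is None:
        raise ValueError("mode='averaged' requires the sample metadata")
    cond_of = meta.table.set_index("sample_id")["replicate_of"]
    by_cond: dict[str, list[str]] = {}
    for col in diffs.columns:
        a, _ = col.split("|", 1)
        by_cond.setdefault(str(cond_of[a]), []).append(col)
    out = {cond: diffs[cols].mean(axis=1) for cond, cols in sorted(by_cond.items())}
    return pd.DataFrame(out, index=diffs.index)


def _report(gene_ids, stat, p, testable, alpha, name) -> pd.DataFrame:
    passed = testable & (p < alpha)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "statistic": stat,
            "p_value": p,
            "passed": passed,
            "testable": testable,
            "filter_name": name,
        }
    ).set_index("gene_id", drop=False)


def technical_error_filter(sib_diffs: pd.DataFrame, tech_diffs: pd.DataFrame,
                           alpha: float = 0.01, *,
                           method: str = "auto") -> pd.DataFrame:
    """One-sided test that sibling differences exceed technical differences.

    Both inputs are genes x values DataFrames sharing a gene index.  A gene
    passes when its sibling-pair differences are significantly
    (``p < alpha``) stochastically larger than its technical-replicate
    differences.  Genes with fewer than two values on either side are flagged
    untestable and never pass.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if not sib_diffs.index.equals(tech_diffs.index):
        raise ValueError("sibling and technical tables must share a gene index")
    if sib_diffs.shape[1] < 2 or tech_diffs.shape[1] < 2:
        # degenerate design: nothing is testable
        n = len(sib_diffs)
        return _report(sib_diffs.index, np.full(n, np.nan), np.full(n, np.nan),
                       np.zeros(n, dtype=bool), alpha, "technical_error")
    u, p = rank_sum_test_matrix(
        sib_diffs.to_numpy(), tech_diffs.to_numpy(),
        alternative="greater", method=method,
    )
    testable = np.ones(len(sib_diffs), dtype=bool)
    return _report(sib_diffs.index, u, p, testable, alpha, "technical_error")


def differential_mean_filter(m_a: ExpressionMatrix, m_b: ExpressionMatrix,
                             alpha: float = 0.01, *,
                             method: str = "auto") -> pd.DataFrame:
    """Two-sided per-gene rank-sum test between two populations.

    Compares each gene's per-individual expression values (all individuals,
    regardless of sex or sibling relationship).  Both matrices must be on the
    log scale and carry the same gene universe.
    """
    if not (0 < alpha <= 1):
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    if m_a.units != "log10" or m_b.units != "log10":
        raise ValueError("differential_mean_filter expects log10-scale matrices")
    if not m_a.data.index.equals(m_b.data.index):
        only_a = m_a.data.index.difference(m_b.data.index)
        only_b = m_b.data.index.difference(m_a.data.index)
        raise ValueError(
            "gene universe mismatch between populations "
            f"(first only: {list(only_a[:3])}, second only: {list(only_b[:3])})"
        )
    u, p = rank_sum_test_matrix(
        m_a.data.to_numpy(), m_b.data.to_numpy(),
        alternative="two-sided", method=method,
    )
    testable = np.ones(len(m_a.data), dtype=bool)
    return _report(m_a.data.index, u, p, testable, alpha, "differential_mean")
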