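"""Per-gene expression variation/diversity and the running-median correction.

For a pair design P, the raw variation of gene j is the average of
``|x_j^i - x_j^k|`` over all pairs (i, k) in P.  Because the magnitude of
expression differences depends strongly on a gene's mean expression level,
a running median over genes of neighbouring mean expression is subtracted:
genes are ranked by mean expression, and the median raw variation within a
window of +-(w-1)/2 neighbours is the expected variation at that expression
level.  The corrected value (raw minus running median) is the
mean-independent stability/diversity score; roughly half the genes are
negative by construction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .filters import pair_differences
from .pairing import PairSet
from .preprocess import ExpressionMatrix

__all__ = ["pairwise_variation", "running_median_correction"]

DEFAULT_WINDOW = 501  # +-250 genes of similar mean expression


def pairwise_variation(m: ExpressionMatrix, pairs: PairSet) -> pd.DataFrame:
    """Average absolute pairwise expression difference per gene.

    Returns a GeneVariationTable: DataFrame indexed by gene with columns
    ``mean_expression`` (mean log expression over the individuals referenced
    by the PairSet), ``raw_variation``, ``pairset_kind`` and ``stage``.
    """
    diffs = pair_differences(m, pairs)
    individuals = pairs.sample_ids()
    table = pd.DataFrame(
        {
            "gene_id": m.data.index,
            "mean_expression": m.data[individuals].mean(axis=1).to_numpy(),
            "raw_variation": diffs.mean(axis=1).to_numpy(),
            "pairset_kind": pairs.kind,
            "stage": pairs.stage,
        }
    ).set_index("gene_id", drop=False)
    return table


def _running_median(values: np.ndarray, window: int) -> np.ndarray:
    """Running median with symmetric edge shrink.

    At rank r of n sorted genes the half-width is ``min((window-1)//2, r,
    n-1-r)``: near the edges the window shrinks to keep an equal number of
    genes on each side, so every slice has odd length.
    """
    n = len(values)
    halfw = (window - 1) // 2
    out = np.empty(n)
    if n > 2 * halfw:
        # interior: fixed odd window, vectorised via pandas rolling median
        interior = (
            pd.Series(values).rolling(window, center=True).median().to_numpy()
        )
        out[halfw : n - halfw] = interior[halfw : n - halfw]
        edge_ranks = list(range(halfw)) + list(range(n - halfw, n))
    else:
        edge_ranks = list(range(n))
    for r in edge_ranks:
        h = min(halfw, r, n - 1 - r)
        out[r] = np.median(values[r - h : r + h + 1])
    return out


def running_median_correction(table: pd.DataFrame,
                              window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Subtract the running median of raw variation along mean expression.

    Genes are sorted by (mean_expression, gene_id) — the id as a
    deterministic tie-break — the running median computed with the symmetric
    edge-shrink rule, and ``corrected_variation = raw_variation -
    running_median`` attached.  The input gene order is restored.
    """
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window < 3:
        raise ValueError(f"window must be >= 3, got {window}")
    for col in ("mean_expression", "raw_variation"):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    out = table.copy()
    order = np.lexsort((out["gene_id"].to_numpy(), out["mean_expression"].to_numpy()))
    raw_sorted = out["raw_variation"].to_numpy()[order]
    med_sorted = _running_median(raw_sorted, window)
    med = np.empty_like(med_sorted)
    med[order] = med_sorted
    out["running_median"] = med
    out["corrected_variation"] = out["raw_variation"] - med
    return out
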