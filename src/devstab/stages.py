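"""Whole-transcriptome stage stability: the per-pair variance statistic.

For a pair of embryos (i, k) and the N analysed genes, let
``y_j = x_j^i - x_j^k`` be the per-gene log-expression difference.  The
pair's transcriptome divergence is the population variance

    V^ik = (1/N) * sum_j (y_j - mean(y))^2

(divisor N, not N-1).  Low V across sibling pairs marks a developmentally
stable stage; low V across hybrid-descendant pairs marks an evolutionarily
conserved stage.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pairing import PairSet
from .preprocess import ExpressionMatrix

__all__ = ["pair_variance", "stage_variances"]


def pair_variance(m: ExpressionMatrix, i: str, k: str, genes=None) -> float:
    """Population variance of per-gene expression differences between two samples."""
    if m.units != "log10":
        raise ValueError("pair_variance expects log10-scale values")
    for s in (i, k):
        if s not in m.data.columns:
            raise ValueError(f"sample {s!r} not in matrix")
    data = m.data if genes is None else m.data.loc[list(genes)]
    if len(data) < 2:
        raise ValueError(f"need >=2 genes, got {len(data)}")
    y = data[i].to_numpy() - data[k].to_numpy()
    return float(np.var(y))  # ddof=0: divisor N


def stage_variances(m: ExpressionMatrix, pairs: PairSet, genes=None, *,
                    group: str = "") -> pd.DataFrame:
    """V^ik for every pair of a PairSet, as a StageVarianceTable.

    Returns a DataFrame with columns group, stage, sample_a, sample_b, v and
    n_genes (the size of the analysed gene set).
    """
    if len(pairs) == 0:
        raise ValueError("empty PairSet")
    data = m.data if genes is None else m.data.loc[list(genes)]
    if len(data) < 2:
        raise ValueError(f"need >=2 genes, got {len(data)}")
    values = data.to_numpy()
    col_index = {s: j for j, s in enumerate(data.columns)}
    rows = []
    for a, b in pairs.pairs:
        for s in (a, b):
            if s not in col_index:
                raise ValueError(f"sample {s!r} not in matrix")
        y = values[:, col_index[a]] - values[:, col_index[b]]
        rows.append((group, pairs.stage, a, b, float(np.var(y)), len(data)))
    return pd.DataFrame(
        rows, columns=["group", "stage", "sample_a", "sample_b", "v", "n_genes"]
    )
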