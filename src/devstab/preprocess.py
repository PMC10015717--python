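"""Expression-matrix containers, I/O, log transform and low-expression filtering.

Expression values arrive as TPM (transcripts per million) with genes in rows
and samples in columns; every downstream statistic works on the
``log10(TPM + 1)`` scale.  Genes whose log expression never reaches a
detection threshold in any sample are excluded before any pairwise statistic
is computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "read_expression",
    "read_metadata",
    "write_expression",
    "log_transform",
    "filter_low_expression",
]

#: recognised expression units
UNITS = ("tpm", "log10")

REQUIRED_META_COLUMNS = ("sample_id", "stage", "group")
OPTIONAL_META_COLUMNS = ("sex", "sibling_group", "replicate_of")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with an explicit unit flag.

    Parameters
    ----------
    data
        DataFrame indexed by gene id, one column per sample id.
    units
        ``"tpm"`` for linear-scale relative expression, ``"log10"`` for
        ``log10(TPM + 1)`` values.
    """

    data: pd.DataFrame
    units: str = "tpm"

    def __post_init__(self) -> None:
        if self.units not in UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {UNITS}")
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dup[:5]}")
        cols = self.data.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dup[:5]}")
        values = self.data.to_numpy()
        if values.size and not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        if values.size and values.min() < 0:
            raise ValueError("expression values must be non-negative")

    # -- convenience accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.data.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(gene_ids)], self.units)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)], self.units)


@dataclass
class SampleMetadata:
    """Per-sample design annotations (stage, group, sex, sibling group)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_META_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"metadata missing required columns: {missing}")
        tab = self.table.copy()
        for col in OPTIONAL_META_COLUMNS:
            if col not in tab.columns:
                tab[col] = pd.NA
        for col in REQUIRED_META_COLUMNS + OPTIONAL_META_COLUMNS:
            tab[col] = tab[col].astype("string")
        if tab["sample_id"].duplicated().any():
            dup = tab.loc[tab["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValueError(f"duplicate sample ids in metadata: {dup[:5]}")
        self.table = tab.reset_index(drop=True)

    def select(self, **criteria: str) -> pd.DataFrame:
        """Rows matching all equality ``criteria`` (e.g. stage="28", group="F0")."""
        mask = pd.Series(True, index=self.table.index)
        for col, value in criteria.items():
            if col not in self.table.columns:
                raise KeyError(f"unknown metadata column {col!r}")
            mask &= self.table[col] == str(value)
        return self.table[mask]

    def stages(self) -> list[str]:
        return sorted(self.table["stage"].dropna().unique().tolist())

    def require_samples(self, sample_ids) -> None:
        known = set(self.table["sample_id"])
        unknown = [s for s in sample_ids if s not in known]
        if unknown:
            raise ValueError(f"samples missing from metadata: {unknown[:5]}")


# -- I/O ----------------------------------------------------------------------

def read_expression(path, *, sep: str = "\t", gene_column: str | int = 0,
                    units: str = "tpm") -> ExpressionMatrix:
    """Read a delimited genes-x-samples expression table.

    The gene-id column may be named (``gene_column="gene_id"``) or given by
    position (default: first column).  Non-numeric cells and duplicate gene
    ids raise with the offending row/column named.
    """
    df = pd.read_csv(path, sep=sep, dtype={0: str} if gene_column == 0 else None)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise ValueError(f"no genes parsed from {path}")
    if isinstance(gene_column, int):
        gene_column = df.columns[gene_column]
    if gene_column not in df.columns:
        raise ValueError(f"gene-id column {gene_column!r} not found in {path}")
    df = df.set_index(gene_column)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene id(s) in {path}: {dup[:5]}")
    for col in df.columns:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"non-numeric value in sample column {col!r}: {exc}") from exc
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), units=units)


def write_expression(m: ExpressionMatrix, path, *, sep: str = "\t",
                     gene_column: str = "gene_id", float_format: str = "%.10g") -> None:
    """Write an expression matrix deterministically (stable row/column order)."""
    out = m.data.copy()
    out.index.name = gene_column
    out.to_csv(path, sep=sep, float_format=float_format)


def read_metadata(path, *, sep: str = "\t") -> SampleMetadata:
    """Read the sample-metadata table (TSV with sample_id/stage/group columns)."""
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.shape[0] == 0:
        raise ValueError(f"no metadata rows parsed from {path}")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path, *, sep: str = "\t") -> None:
    meta.table.to_csv(path, sep=sep, index=False)


# -- transforms ----------------------------------------------------------------

def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return ``log10(TPM + 1)`` copy of a TPM-scale matrix."""
    if m.units != "tpm":
        raise ValueError(f"log_transform expects TPM units, got {m.units!r}")
    values = m.data.to_numpy()
    if values.size and values.min() < 0:
        raise ValueError("negative TPM value encountered")
    return ExpressionMatrix(np.log10(m.data + 1.0), units="log10")


def inverse_log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Back-transform ``log10(TPM + 1)`` values to TPM."""
    if m.units != "log10":
        raise ValueError(f"expected log10 units, got {m.units!r}")
    return ExpressionMatrix(10.0 ** m.data - 1.0, units="tpm")


def filter_low_expression(m: ExpressionMatrix, threshold: float = 0.1) -> ExpressionMatrix:
    """Drop genes whose log expression is below ``threshold`` in every sample.

    A gene is retained as soon as a single sample reaches the threshold;
    gene order is preserved.  The default cutoff of 0.1 log10 units
    corresponds to ~0.26 TPM; results are typically insensitive to cutoffs
    in the 0-1.5 range.
    """
    if m.units != "log10":
        raise ValueError("filter_low_expression expects log10-scale values")
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    keep = (m.data.to_numpy() >= threshold).any(axis=1)
    return ExpressionMatrix(m.data.loc[keep], units="log10")
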