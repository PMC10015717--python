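"""Sample-pair designs over which expression differences are averaged.

Three pairing schemes are used:

* sibling pairs — sex-matched pairs within an inbred sibling group (the
  developmental-stability design);
* all pairs — every unordered pair of embryos in a group at a stage (the
  hybrid-descendant diversity design);
* cross-population pairs — every sex-matched pair spanning two wild
  populations.

Technical-replicate pairs (all combinations of replicates of one condition)
are provided for the measurement-error floor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .preprocess import SampleMetadata

__all__ = [
    "PairSet",
    "sibling_pairs",
    "all_pairs",
    "cross_population_pairs",
    "technical_pairs",
]

PAIR_KINDS = ("sibling", "technical", "hybrid_all_pairs", "cross_population")


@dataclass
class PairSet:
    """An explicit list of unordered sample pairs of one pairing kind."""

    kind: str
    stage: str
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in PAIR_KINDS:
            raise ValueError(f"unknown pair kind {self.kind!r}")
        seen: set[frozenset[str]] = set()
        for a, b in self.pairs:
            if a == b:
                raise ValueError(f"self-pair ({a}, {b}) not allowed")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate unordered pair ({a}, {b})")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.pairs)

    def sample_ids(self) -> list[str]:
        """Unique sample ids referenced by the pairs, in first-seen order."""
        seen: dict[str, None] = {}
        for a, b in self.pairs:
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kind": self.kind,
                "stage": self.stage,
                "sample_a": [a for a, _ in self.pairs],
                "sample_b": [b for _, b in self.pairs],
            }
        )


def _stage_rows(meta: SampleMetadata, stage, group) -> pd.DataFrame:
    rows = meta.select(stage=str(stage), group=str(group))
    return rows.sort_values("sample_id").reset_index(drop=True)


def sibling_pairs(meta: SampleMetadata, stage, *, group: str = "F0",
                  disjoint: bool = False) -> PairSet:
    """Sex-matched pairs of siblings within each sibling group.

    With ``disjoint=True`` each sample enters at most one pair (pairs taken
    in sample-id order); by default all within-group sex-matched pairs are
    formed.  Samples of unknown sex are never matched.
    """
    rows = _stage_rows(meta, stage, group)
    if rows.empty:
        raise ValueError(f"no {group} samples at stage {stage}")
    pairs: list[tuple[str, str]] = []
    reasons: list[str] = []
    for (fam, sex), sub in rows.groupby(["sibling_group", "sex"], dropna=False):
        ids = sub["sample_id"].tolist()
        if pd.isna(fam):
            reasons.append(f"{len(ids)} sample(s) without sibling_group")
            continue
        if pd.isna(sex):
            reasons.append(f"group {fam}: {len(ids)} sample(s) of unknown sex")
            continue
        if len(ids) < 2:
            reasons.append(f"group {fam}/{sex}: singleton")
            continue
        if disjoint:
            pairs.extend((ids[i], ids[i + 1]) for i in range(0, len(ids) - 1, 2))
        else:
            pairs.extend(itertools.combinations(ids, 2))
    if not pairs:
        detail = "; ".join(reasons) or "no sibling groups found"
        raise ValueError(f"no valid sibling pair at stage {stage}: {detail}")
    return PairSet("sibling", str(stage), pairs)


def all_pairs(meta: SampleMetadata, stage, group) -> PairSet:
    """All n(n-1)/2 unordered pairs of the group's embryos at a stage."""
    rows = _stage_rows(meta, stage, group)
    if len(rows) < 2:
        raise ValueError(
            f"need >=2 {group} samples at stage {stage}, found {len(rows)}"
        )
    ids = rows["sample_id"].tolist()
    return PairSet("hybrid_all_pairs", str(stage), list(itertools.combinations(ids, 2)))


def cross_population_pairs(meta: SampleMetadata, stage, pop_a: str, pop_b: str) -> PairSet:
    """All sex-matched pairs spanning two populations at a stage.

    With :math:`n_a` and :math:`n_b` individuals of a given sex the scheme
    contributes the full :math:`n_a n_b` bipartite product for that sex.
    """
    rows_a = _stage_rows(meta, stage, pop_a)
    rows_b = _stage_rows(meta, stage, pop_b)
    if rows_a.empty or rows_b.empty:
        raise ValueError(
            f"both populations required at stage {stage}: "
            f"{pop_a} n={len(rows_a)}, {pop_b} n={len(rows_b)}"
        )
    pairs: list[tuple[str, str]] = []
    for sex in sorted(set(rows_a["sex"].dropna()) & set(rows_b["sex"].dropna())):
        ids_a = rows_a.loc[rows_a["sex"] == sex, "sample_id"]
        ids_b = rows_b.loc[rows_b["sex"] == sex, "sample_id"]
        pairs.extend(itertools.product(ids_a, ids_b))
    if not pairs:
        raise ValueError(
            f"no sex-matched {pop_a}/{pop_b} pair at stage {stage} "
            "(no shared known sex)"
        )
    return PairSet("cross_population", str(stage), pairs)


def technical_pairs(meta: SampleMetadata, stage, *, group: str = "tech") -> PairSet:
    """All replicate-pair combinations within each technical condition.

    Four replicates of a condition yield the six pairwise combinations used
    to estimate the technical-error floor.
    """
    rows = _stage_rows(meta, stage, group)
    if rows.empty:
        raise ValueError(f"no technical replicates at stage {stage}")
    pairs: list[tuple[str, str]] = []
    for cond, sub in rows.groupby("replicate_of", dropna=False):
        ids = sub["sample_id"].tolist()
        if pd.isna(cond) or len(ids) < 2:
            continue
        pairs.extend(itertools.combinations(ids, 2))
    if not pairs:
        raise ValueError(
            f"no technical replicate pair at stage {stage} "
            "(replicate_of missing or singleton conditions)"
        )
    return PairSet("technical", str(stage), pairs)


def check_pairset(ps: PairSet, meta: SampleMetadata) -> None:
    """Re-validate a PairSet's matching predicate against the metadata."""
    tab = meta.table.set_index("sample_id")
    for a, b in ps.pairs:
        ra, rb = tab.loc[a], tab.loc[b]
        if ps.kind == "sibling":
            ok = (ra["sibling_group"] == rb["sibling_group"]
                  and pd.notna(ra["sex"]) and ra["sex"] == rb["sex"])
        elif ps.kind == "cross_population":
            ok = (ra["group"] != rb["group"]
                  and pd.notna(ra["sex"]) and ra["sex"] == rb["sex"])
        elif ps.kind == "technical":
            ok = ra["replicate_of"] == rb["replicate_of"]
        else:  # hybrid_all_pairs
            ok = ra["group"] == rb["group"] and ra["stage"] == rb["stage"]
        if not bool(ok):
            raise AssertionError(f"pair ({a}, {b}) violates {ps.kind} predicate")
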