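"""End-to-end orchestration of the developmental-stability analysis.

Three entry points mirror the study's result layers:

* :func:`run_gene_level` — per stage, founder (F0) sibling-pair expression
  variation vs descendant (F3) all-pairs diversity, both running-median
  corrected, correlated by Spearman's rho;
* :func:`run_wild_comparison` — per stage, F3 diversity vs cross-population
  diversity between two wild populations;
* :func:`run_stage_level` — per-pair whole-transcriptome variance V^ik per
  stage and group, with Kruskal-Wallis + Steel-Dwass stage comparisons.

Each stage is processed with its own gene set and pair design; cross-stage
comparisons only ever see the per-pair V^ik distributions.  All intermediate
tables can be serialized as TSV, and :func:`verify_outputs` re-derives every
reported headline number from the serialized intermediates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import filters, pairing, stages as stage_metrics, stats, variation
from .preprocess import (
    ExpressionMatrix,
    SampleMetadata,
    filter_low_expression,
    log_transform,
)

logger = logging.getLogger("devstab")

__all__ = [
    "PipelineParams",
    "run_gene_level",
    "run_wild_comparison",
    "run_stage_level",
    "write_gene_level",
    "write_wild_comparison",
    "write_stage_level",
    "verify_outputs",
]

FLOAT_FMT = "%.10g"


@dataclass
class PipelineParams:
    """Tunable thresholds and switches of the analysis."""

    low_expression_threshold: float = 0.1
    tech_alpha: float = 0.01
    diff_alpha: float = 0.01
    correction_window: int = 501
    #: opt-in F0-vs-F3 differential-mean gene selection
    apply_differential_mean_filter: bool = False
    #: 'pairwise' (six replicate-pair differences) or 'averaged'
    tech_mode: str = "pairwise"
    sibling_disjoint: bool = False
    rank_method: str = "auto"
    f0_group: str = "F0"
    f3_group: str = "F3"
    tech_group: str = "tech"
    wild_populations: tuple[str, str] = ("Kasasa", "Oura")
    #: force one gene set for both groups in the stage-level analysis
    common_gene_set: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.low_expression_threshold <= 1.5:
            raise ValueError("low_expression_threshold must be in [0, 1.5]")


@dataclass
class StageGeneResult:
    stage: str
    f0_table: pd.DataFrame
    f3_table: pd.DataFrame
    tech_report: pd.DataFrame
    diff_report: pd.DataFrame | None
    correlation: stats.CorrelationResult
    gene_counts: dict[str, int]


@dataclass
class GeneLevelResult:
    stages: dict[str, StageGeneResult] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "stage": s,
                "rho": r.correlation.rho,
                "p_value": r.correlation.p_value,
                "n_genes": r.correlation.n,
            }
            for s, r in self.stages.items()
        ]
        return pd.DataFrame(rows, columns=["stage", "rho", "p_value", "n_genes"])


@dataclass
class StageWildResult:
    stage: str
    f3_table: pd.DataFrame
    wild_table: pd.DataFrame
    correlation: stats.CorrelationResult
    gene_counts: dict[str, int]


@dataclass
class WildComparisonResult:
    stages: dict[str, StageWildResult] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "stage": s,
                "rho": r.correlation.rho,
                "p_value": r.correlation.p_value,
                "n_genes": r.correlation.n,
            }
            for s, r in self.stages.items()
        ]
        return pd.DataFrame(rows, columns=["stage", "rho", "p_value", "n_genes"])


@dataclass
class StageLevelResult:
    variances: pd.DataFrame
    comparisons: dict[str, stats.GroupComparisonResult]

    def summary(self) -> pd.DataFrame:
        rows = []
        for group, comp in self.comparisons.items():
            for a, b, z, p in comp.pairwise:
                rows.append(
                    {
                        "group": group,
                        "stage_a": a,
                        "stage_b": b,
                        "z": z,
                        "p_value": p,
                        "omnibus_p": comp.omnibus_p,
                    }
                )
        return pd.DataFrame(
            rows, columns=["group", "stage_a", "stage_b", "z", "p_value", "omnibus_p"]
        )

    def medians(self) -> pd.DataFrame:
        return (
            self.variances.groupby(["group", "stage"], as_index=False)["v"]
            .median()
            .rename(columns={"v": "median_v"})
        )


# -- shared plumbing -----------------------------------------------------------

def _as_log(expr: ExpressionMatrix) -> ExpressionMatrix:
    return log_transform(expr) if expr.units == "tpm" else expr


def _group_matrix(log_expr: ExpressionMatrix, meta: SampleMetadata, stage, group,
                  threshold: float) -> ExpressionMatrix | None:
    rows = meta.select(stage=str(stage), group=group)
    ids = [s for s in rows["sample_id"] if s in log_expr.data.columns]
    if not ids:
        return None
    return filter_low_expression(log_expr.subset_samples(ids), threshold)


def _stage_gene_universe(*matrices: ExpressionMatrix) -> pd.Index:
    universe = matrices[0].gene_ids
    for m in matrices[1:]:
        universe = universe.intersection(m.gene_ids, sort=False)
    return universe


def _tech_pass_genes(log_expr, meta, stage, universe, params) -> tuple[pd.Index, pd.DataFrame]:
    """Genes whose sibling variation exceeds the technical floor at a stage."""
    sib = pairing.sibling_pairs(meta, stage, group=params.f0_group,
                                disjoint=params.sibling_disjoint)
    tech = pairing.technical_pairs(meta, stage, group=params.tech_group)
    sub = log_expr.subset_genes(universe)
    sib_diffs = filters.pair_differences(sub, sib)
    tech_vals = filters.technical_error_values(sub, tech, meta, mode=params.tech_mode)
    report = filters.technical_error_filter(
        sib_diffs, tech_vals, params.tech_alpha, method=params.rank_method
    )
    return report.index[report["passed"]], report


def _corrected_variation(m: ExpressionMatrix, pairs: pairing.PairSet,
                         genes, window: int) -> pd.DataFrame:
    table = variation.pairwise_variation(m.subset_genes(genes), pairs)
    return variation.running_median_correction(table, window)


# -- gene level ----------------------------------------------------------------

def run_gene_level(expr: ExpressionMatrix, meta: SampleMetadata,
                   params: PipelineParams | None = None,
                   stages=None) -> GeneLevelResult:
    """Founder variation vs descendant diversity, per gene and stage."""
    params = params or PipelineParams()
    log_expr = _as_log(expr)
    result = GeneLevelResult()
    for stage in stages or meta.stages():
        try:
            result.stages[stage] = _gene_level_stage(log_expr, meta, stage, params)
        except ValueError as exc:
            logger.warning("gene-level: skipping stage %s: %s", stage, exc)
            result.skipped[stage] = str(exc)
    if not result.stages:
        raise ValueError(f"no stage could be analysed: {result.skipped}")
    return result


def _gene_level_stage(log_expr, meta, stage, params) -> StageGeneResult:
    thr = params.low_expression_threshold
    m_f0 = _group_matrix(log_expr, meta, stage, params.f0_group, thr)
    m_f3 = _group_matrix(log_expr, meta, stage, params.f3_group, thr)
    if m_f0 is None or m_f3 is None:
        raise ValueError(f"missing {params.f0_group} or {params.f3_group} samples")
    universe = _stage_gene_universe(m_f0, m_f3)
    counts = {"universe": len(universe)}
    genes, tech_report = _tech_pass_genes(log_expr, meta, stage, universe, params)
    counts["tech_pass"] = len(genes)

    diff_report = None
    if params.apply_differential_mean_filter:
        diff_report = filters.differential_mean_filter(
            m_f0.subset_genes(genes), m_f3.subset_genes(genes),
            params.diff_alpha, method=params.rank_method,
        )
        genes = diff_report.index[diff_report["passed"]]
        counts["diff_mean_pass"] = len(genes)
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} genes survive filtering")

    sib = pairing.sibling_pairs(meta, stage, group=params.f0_group,
                                disjoint=params.sibling_disjoint)
    f3_pairs = pairing.all_pairs(meta, stage, params.f3_group)
    f0_table = _corrected_variation(m_f0, sib, genes, params.correction_window)
    f3_table = _corrected_variation(m_f3, f3_pairs, genes, params.correction_window)
    corr = stats.spearman_test(
        f0_table.loc[genes, "corrected_variation"],
        f3_table.loc[genes, "corrected_variation"],
    )
    logger.info(
        "gene-level stage %s: universe=%d tech_pass=%d pairs F0=%d F3=%d rho=%.3f",
        stage, counts["universe"], counts["tech_pass"], len(sib), len(f3_pairs),
        corr.rho,
    )
    return StageGeneResult(str(stage), f0_table, f3_table, tech_report,
                           diff_report, corr, counts)


# -- wild comparison -----------------------------------------------------------

def run_wild_comparison(expr: ExpressionMatrix, meta: SampleMetadata,
                        params: PipelineParams | None = None,
                        stages=None) -> WildComparisonResult:
    """Descendant diversity vs wild cross-population diversity, per stage."""
    params = params or PipelineParams()
    log_expr = _as_log(expr)
    result = WildComparisonResult()
    for stage in stages or meta.stages():
        try:
            result.stages[stage] = _wild_stage(log_expr, meta, stage, params)
        except ValueError as exc:
            logger.warning("wild-comparison: skipping stage %s: %s", stage, exc)
            result.skipped[stage] = str(exc)
    if not result.stages:
        raise ValueError(f"no stage could be analysed: {result.skipped}")
    return result


def _wild_stage(log_expr, meta, stage, params) -> StageWildResult:
    thr = params.low_expression_threshold
    pop_a, pop_b = params.wild_populations
    m_f3 = _group_matrix(log_expr, meta, stage, params.f3_group, thr)
    m_a = _group_matrix(log_expr, meta, stage, pop_a, thr)
    m_b = _group_matrix(log_expr, meta, stage, pop_b, thr)
    if m_f3 is None:
        raise ValueError(f"missing {params.f3_group} samples")
    if m_a is None or m_b is None:
        raise ValueError(f"missing wild population ({pop_a}/{pop_b}) samples")
    universe = _stage_gene_universe(m_f3, m_a, m_b)
    counts = {"universe": len(universe)}
    try:
        genes, _ = _tech_pass_genes(log_expr, meta, stage, universe, params)
        counts["tech_pass"] = len(genes)
    except ValueError:
        # no founder/technical data available: analyse the full universe
        genes = universe
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} genes survive filtering")

    f3_pairs = pairing.all_pairs(meta, stage, params.f3_group)
    cross = pairing.cross_population_pairs(meta, stage, pop_a, pop_b)
    wild_ids = cross.sample_ids()
    m_wild = filter_low_expression(
        log_expr.subset_samples(wild_ids), params.low_expression_threshold
    )
    genes = pd.Index(genes).intersection(m_wild.gene_ids, sort=False)
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} genes shared with wild data")
    f3_table = _corrected_variation(m_f3, f3_pairs, genes, params.correction_window)
    wild_table = _corrected_variation(m_wild, cross, genes, params.correction_window)
    corr = stats.spearman_test(
        f3_table.loc[genes, "corrected_variation"],
        wild_table.loc[genes, "corrected_variation"],
    )
    logger.info(
        "wild stage %s: genes=%d cross pairs=%d rho=%.3f",
        stage, len(genes), len(cross), corr.rho,
    )
    return StageWildResult(str(stage), f3_table, wild_table, corr, counts)


# -- stage level ---------------------------------------------------------------

def run_stage_level(expr: ExpressionMatrix, meta: SampleMetadata,
                    params: PipelineParams | None = None,
                    stages=None) -> StageLevelResult:
    """Whole-transcriptome V^ik per pair, with stage comparisons per group."""
    params = params or PipelineParams()
    log_expr = _as_log(expr)
    stage_list = list(stages or meta.stages())
    if len(stage_list) < 2:
        raise ValueError("need >=2 stages for stage-level comparisons")
    thr = params.low_expression_threshold
    tables = []
    for stage in stage_list:
        m_f0 = _group_matrix(log_expr, meta, stage, params.f0_group, thr)
        m_f3 = _group_matrix(log_expr, meta, stage, params.f3_group, thr)
        if m_f0 is None and m_f3 is None:
            logger.warning("stage-level: no data at stage %s", stage)
            continue
        gene_sets: dict[str, pd.Index] = {}
        if m_f0 is not None:
            tech_pass, _ = _tech_pass_genes(log_expr, meta, stage,
                                            m_f0.gene_ids, params)
            gene_sets[params.f0_group] = tech_pass
            if m_f3 is not None:
                gene_sets[params.f3_group] = pd.Index(tech_pass).intersection(
                    m_f3.gene_ids, sort=False
                )
        elif m_f3 is not None:
            gene_sets[params.f3_group] = m_f3.gene_ids
        if params.common_gene_set and len(gene_sets) == 2:
            common = gene_sets[params.f0_group].intersection(
                gene_sets[params.f3_group], sort=False
            )
            gene_sets = {g: common for g in gene_sets}
        if m_f0 is not None:
            sib = pairing.sibling_pairs(meta, stage, group=params.f0_group,
                                        disjoint=params.sibling_disjoint)
            tables.append(
                stage_metrics.stage_variances(
                    m_f0, sib, gene_sets[params.f0_group], group=params.f0_group
                )
            )
        if m_f3 is not None:
            f3_pairs = pairing.all_pairs(meta, stage, params.f3_group)
            tables.append(
                stage_metrics.stage_variances(
                    m_f3, f3_pairs, gene_sets[params.f3_group], group=params.f3_group
                )
            )
    if not tables:
        raise ValueError("no stage produced V^ik values")
    variances = pd.concat(tables, ignore_index=True)
    comparisons: dict[str, stats.GroupComparisonResult] = {}
    for group, sub in variances.groupby("group"):
        present = [s for s in stage_list if s in set(sub["stage"])]
        if len(present) < 2:
            logger.warning("stage-level: group %s has <2 stages, skipping tests", group)
            continue
        values = [sub.loc[sub["stage"] == s, "v"].to_numpy() for s in present]
        comparisons[group] = stats.compare_groups(values, labels=present)
        logger.info("stage-level %s: KW p=%.3g over stages %s",
                    group, comparisons[group].omnibus_p, present)
    return StageLevelResult(variances, comparisons)


# -- serialization and audit ---------------------------------------------------

def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _stage_tag(stage: str) -> str:
    return str(stage).replace(".", "_")


def write_gene_level(result: GeneLevelResult, outdir) -> None:
    out = Path(outdir) / "gene_level"
    for stage, res in result.stages.items():
        tag = _stage_tag(stage)
        _write_tsv(res.f0_table.reset_index(drop=True), out / f"f0_variation_{tag}.tsv")
        _write_tsv(res.f3_table.reset_index(drop=True), out / f"f3_diversity_{tag}.tsv")
        _write_tsv(res.tech_report.reset_index(drop=True), out / f"tech_filter_{tag}.tsv")
        if res.diff_report is not None:
            _write_tsv(res.diff_report.reset_index(drop=True),
                       out / f"diff_mean_filter_{tag}.tsv")
    _write_tsv(result.summary(), out / "summary.tsv")


def write_wild_comparison(result: WildComparisonResult, outdir) -> None:
    out = Path(outdir) / "wild_comparison"
    for stage, res in result.stages.items():
        tag = _stage_tag(stage)
        _write_tsv(res.f3_table.reset_index(drop=True), out / f"f3_diversity_{tag}.tsv")
        _write_tsv(res.wild_table.reset_index(drop=True), out / f"wild_diversity_{tag}.tsv")
    _write_tsv(result.summary(), out / "summary.tsv")


def write_stage_level(result: StageLevelResult, outdir) -> None:
    out = Path(outdir) / "stage_level"
    _write_tsv(result.variances, out / "stage_variances.tsv")
    _write_tsv(result.summary(), out / "steel_dwass.tsv")
    _write_tsv(result.medians(), out / "medians.tsv")
    omnibus = pd.DataFrame(
        [
            {"group": g, "kruskal_h": c.omnibus_statistic, "kruskal_p": c.omnibus_p}
            for g, c in result.comparisons.items()
        ]
    )
    _write_tsv(omnibus, out / "kruskal.tsv")


def verify_outputs(outdir, *, atol: float = 1e-8) -> list[str]:
    """Re-derive headline numbers from serialized intermediates and diff them.

    Returns a list of human-readable mismatch descriptions (empty = verified).
    """
    out = Path(outdir)
    problems: list[str] = []

    for sub, (x_file, y_file) in {
        "gene_level": ("f0_variation_{tag}.tsv", "f3_diversity_{tag}.tsv"),
        "wild_comparison": ("f3_diversity_{tag}.tsv", "wild_diversity_{tag}.tsv"),
    }.items():
        summary_path = out / sub / "summary.tsv"
        if not summary_path.exists():
            continue
        summary = pd.read_csv(summary_path, sep="\t", dtype={"stage": str})
        for _, row in summary.iterrows():
            tag = _stage_tag(row["stage"])
            tx = pd.read_csv(out / sub / x_file.format(tag=tag), sep="\t")
            ty = pd.read_csv(out / sub / y_file.format(tag=tag), sep="\t")
            merged = tx.merge(ty, on="gene_id", suffixes=("_x", "_y"))
            corr = stats.spearman_test(
                merged["corrected_variation_x"], merged["corrected_variation_y"]
            )
            if abs(corr.rho - row["rho"]) > atol:
                problems.append(
                    f"{sub} stage {row['stage']}: rho {row['rho']} != recomputed {corr.rho}"
                )
            if int(row["n_genes"]) != corr.n:
                problems.append(
                    f"{sub} stage {row['stage']}: n {row['n_genes']} != {corr.n}"
                )

    sd_path = out / "stage_level" / "steel_dwass.tsv"
    if sd_path.exists():
        sd = pd.read_csv(sd_path, sep="\t", dtype={"stage_a": str, "stage_b": str})
        var = pd.read_csv(out / "stage_level" / "stage_variances.tsv", sep="\t",
                          dtype={"stage": str})
        for group, sub_sd in sd.groupby("group"):
            gv = var[var["group"] == group]
            present = sorted(set(gv["stage"]))
            values = [gv.loc[gv["stage"] == s, "v"].to_numpy() for s in present]
            comp = stats.compare_groups(values, labels=present)
            recomputed = {(a, b): p for a, b, _, p in comp.pairwise}
            for _, row in sub_sd.iterrows():
                key = (row["stage_a"], row["stage_b"])
                p = recomputed.get(key, recomputed.get(key[::-1]))
                if p is None or abs(p - row["p_value"]) > atol:
                    problems.append(
                        f"stage_level {group} {key}: p {row['p_value']} != {p}"
                    )
            if abs(comp.omnibus_p - sub_sd["omnibus_p"].iloc[0]) > atol:
                problems.append(
                    f"stage_level {group}: omnibus p mismatch"
                )
    return problems


def write_run_manifest(outdir, info: dict) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(info, fh, indent=2, sort_keys=True)
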