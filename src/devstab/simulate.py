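"""Synthetic expression data with the statistical structure the pipeline assumes.

The generator emulates the sibling-pair crossing design: four developmental
stages; inbred founder (F0) embryos measured as sex-matched sibling pairs
with technical replicates; hybrid third-generation (F3) descendants; and two
wild populations.  On the log10(TPM+1) scale each individual's expression of
gene j is

    x_j = mu_j + s * sd_j * eps,    eps ~ N(0, 1)

where ``mu_j`` is a gene-specific baseline (gamma-distributed across genes),
``s`` is the stage's biological noise scale (smallest at the hourglass
stage) and ``sd_j`` a per-gene noise factor.  ``sd_j`` is the sum of

* a noise *floor* increasing monotonically with ``mu_j`` (planting the
  mean-variance dependence that the running-median correction removes —
  the correction subtracts exactly this additive component), and
* a log-uniform per-gene factor: a *stability* factor for founder embryos
  and a *diversity* factor for descendants, linked through a Gaussian copula
  so that the rank correlation between founder per-gene variation and
  descendant per-gene diversity is planted at ``rho_target``.  The
  log-uniform marginal spreads gene ranks evenly on the log scale, so the
  planted rank structure survives estimation from small embryo counts.

Technical replicates re-measure one founder embryo with small independent
noise.  Wild populations reuse the descendant noise structure plus a
per-gene mean offset between populations.  A configurable fraction of genes
sits below the detection threshold in every sample.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm as _norm

from .preprocess import ExpressionMatrix, SampleMetadata

__all__ = ["GeneratorConfig", "generate", "write_dataset"]

DEFAULT_STAGES = ("15", "23.5", "28", "hatching")


def _stage_map(value, stages) -> dict[str, float]:
    if isinstance(value, dict):
        out = {str(k): v for k, v in value.items()}
    else:
        out = {s: value for s in stages}
    missing = [s for s in stages if s not in out]
    if missing:
        raise ValueError(f"per-stage value missing for stages {missing}")
    return {s: out[s] for s in stages}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic crossing-design generator.

    Defaults mirror the published study design: sibling-pair counts of
    23/24/25/13 across stages 15/23.5/28/hatching, four technical replicates
    of one condition per stage, 5-6 descendant embryos per stage, and 4/4/4/2
    wild individuals per population, with the mid-embryonic stage (28)
    carrying the smallest biological noise scale (the hourglass profile).
    """

    n_genes: int = 10_000
    stages: tuple[str, ...] = DEFAULT_STAGES
    #: per-stage biological noise scale (log10 units); minimal at stage 28
    sigma_stage: dict = field(
        default_factory=lambda: {"15": 0.12, "23.5": 0.11, "28": 0.06, "hatching": 0.13}
    )
    n_sibling_pairs: dict = field(
        default_factory=lambda: {"15": 23, "23.5": 24, "28": 25, "hatching": 13}
    )
    n_tech_replicates: int = 4
    n_f3: dict = field(
        default_factory=lambda: {"15": 5, "23.5": 6, "28": 6, "hatching": 6}
    )
    n_wild: dict = field(
        default_factory=lambda: {"15": 4, "23.5": 4, "28": 4, "hatching": 2}
    )
    wild_populations: tuple[str, str] = ("Kasasa", "Oura")
    #: gamma(shape, scale) + floor for baseline log10 expression across genes
    mean_log_shape: float = 2.2
    mean_log_scale: float = 0.6
    mean_log_floor: float = 0.3
    #: mean-dependent noise floor: floor = trend_floor + trend_span * Phi(z(mu))
    trend_floor: float = 0.1
    trend_span: float = 0.4
    #: natural-log range of the per-gene stability/diversity factors
    #: (factors are log-uniform on [exp(-span/2), exp(span/2)])
    stability_span: float = 4.0
    #: planted Spearman correlation between stability and diversity factors
    rho_target: float = 0.4
    #: overall noise inflation of descendants relative to founders
    f3_inflation: float = 1.3
    wild_scale: float = 1.0
    #: sd of the per-gene mean offset between the two wild populations
    population_offset_sd: float = 0.03
    #: technical replicate noise (log10 units)
    sigma_tech: float = 0.02
    frac_below_detection: float = 0.08
    #: draw noise from a scaled t(5) instead of a normal
    heavy_tails: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.stages = tuple(str(s) for s in self.stages)
        self.sigma_stage = _stage_map(self.sigma_stage, self.stages)
        self.n_sibling_pairs = {
            k: int(v) for k, v in _stage_map(self.n_sibling_pairs, self.stages).items()
        }
        self.n_f3 = {k: int(v) for k, v in _stage_map(self.n_f3, self.stages).items()}
        self.n_wild = {k: int(v) for k, v in _stage_map(self.n_wild, self.stages).items()}
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not -1.0 <= self.rho_target <= 1.0:
            raise ValueError("rho_target must be in [-1, 1]")
        for name in ("sigma_tech", "stability_span", "trend_floor", "trend_span",
                     "population_offset_sd", "wild_scale", "f3_inflation"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(v < 0 for v in self.sigma_stage.values()):
            raise ValueError("sigma_stage values must be >= 0")
        if any(v < 0 for d in (self.n_sibling_pairs, self.n_f3, self.n_wild)
               for v in d.values()):
            raise ValueError("sample counts must be >= 0")
        if not 0.0 <= self.frac_below_detection < 1.0:
            raise ValueError("frac_below_detection must be in [0, 1)")

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["wild_populations"] = list(self.wild_populations)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["stages"] = tuple(d.get("stages", DEFAULT_STAGES))
        if "wild_populations" in d:
            d["wild_populations"] = tuple(d["wild_populations"])
        return cls(**d)


def _noise(rng: np.random.Generator, size, heavy: bool) -> np.ndarray:
    if heavy:
        # t(5) scaled to unit variance
        return rng.standard_t(5, size=size) / math.sqrt(5.0 / 3.0)
    return rng.standard_normal(size)


def generate(cfg: GeneratorConfig):
    """Simulate one dataset.

    Returns ``(expression, metadata, truth)``: a TPM-scale
    :class:`ExpressionMatrix`, the matching :class:`SampleMetadata`, and the
    per-gene truth record (baseline, trend, stability and diversity factors).
    """
    rng = np.random.default_rng(cfg.seed)
    g = cfg.n_genes
    gene_ids = pd.Index([f"g{i:06d}" for i in range(g)], name="gene_id")

    mu = cfg.mean_log_floor + rng.gamma(cfg.mean_log_shape, cfg.mean_log_scale, size=g)
    z = (mu - mu.mean()) / mu.std() if mu.std() > 0 else np.zeros(g)
    floor = cfg.trend_floor + cfg.trend_span * _norm.cdf(z)

    # Gaussian copula linking founder stability to descendant diversity;
    # marginals are log-uniform (median one) over exp(+-stability_span/2)
    r = 2.0 * math.sin(math.pi * cfg.rho_target / 6.0)
    a = rng.standard_normal(g)
    b = r * a + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(g)
    stability = np.exp(cfg.stability_span * (_norm.cdf(a) - 0.5))
    diversity = np.exp(cfg.stability_span * (_norm.cdf(b) - 0.5))

    f0_sd = floor + stability                          # founder per-gene factor
    f3_sd = (floor + diversity) * cfg.f3_inflation     # descendant per-gene factor
    pop_offset = rng.normal(0.0, cfg.population_offset_sd, size=g)

    n_low = int(round(cfg.frac_below_detection * g))
    low_mask = np.zeros(g, dtype=bool)
    if n_low:
        low_mask[rng.choice(g, size=n_low, replace=False)] = True

    columns: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []

    def add(sample_id, values, stage, group, sex=None, sibling_group=None,
            replicate_of=None) -> None:
        columns[sample_id] = values
        meta_rows.append(
            {
                "sample_id": sample_id,
                "stage": stage,
                "group": group,
                "sex": sex,
                "sibling_group": sibling_group,
                "replicate_of": replicate_of,
            }
        )

    pop_a, pop_b = cfg.wild_populations
    for stage in cfg.stages:
        s = cfg.sigma_stage[stage]
        tech_base: np.ndarray | None = None
        for p in range(cfg.n_sibling_pairs[stage]):
            fam = f"s{stage}_fam{p:02d}"
            sex = "M" if p % 2 == 0 else "F"
            for tag in ("a", "b"):
                x = mu + s * f0_sd * _noise(rng, g, cfg.heavy_tails)
                sid = f"f0_s{stage}_p{p:02d}{tag}"
                add(sid, x, stage, "F0", sex=sex, sibling_group=fam)
                if tech_base is None:
                    tech_base = x
                    tech_base_id = sid
        if tech_base is not None and cfg.n_tech_replicates >= 2:
            for t in range(cfg.n_tech_replicates):
                x = tech_base + cfg.sigma_tech * _noise(rng, g, cfg.heavy_tails)
                add(f"tech_s{stage}_r{t}", x, stage, "tech",
                    replicate_of=tech_base_id)
        for e in range(cfg.n_f3[stage]):
            x = mu + s * f3_sd * _noise(rng, g, cfg.heavy_tails)
            add(f"f3_s{stage}_e{e:02d}", x, stage, "F3",
                sex="M" if e % 2 == 0 else "F")
        for pop, offset in ((pop_a, 0.0), (pop_b, 1.0)):
            for e in range(cfg.n_wild[stage]):
                x = (mu + offset * pop_offset
                     + s * f3_sd * cfg.wild_scale * _noise(rng, g, cfg.heavy_tails))
                add(f"{pop.lower()}_s{stage}_e{e:02d}", x, stage, pop, sex="F")

    if not columns:
        raise ValueError("configuration produced no samples")

    log_expr = pd.DataFrame(columns, index=gene_ids).clip(lower=0.0)
    if n_low:
        # below-detection genes: flat, structureless signal under the cutoff
        log_expr.iloc[low_mask.nonzero()[0]] = rng.uniform(
            0.0, 0.08, size=(n_low, log_expr.shape[1])
        )
    tpm = 10.0 ** log_expr - 1.0

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "mu": mu,
            "noise_floor": floor,
            "stability_factor": stability,
            "diversity_factor": diversity,
            "f0_sd_factor": f0_sd,
            "f3_sd_factor": f3_sd,
            "population_offset": pop_offset,
            "below_detection": low_mask,
        }
    ).set_index("gene_id", drop=False)
    truth.attrs["rho_target"] = cfg.rho_target
    truth.attrs["copula_r"] = r
    truth.attrs["sigma_stage"] = dict(cfg.sigma_stage)

    meta = SampleMetadata(pd.DataFrame(meta_rows))
    return ExpressionMatrix(tpm, units="tpm"), meta, truth


def write_dataset(cfg: GeneratorConfig, outdir) -> dict[str, str]:
    """Generate and write expression/metadata/truth/config files to ``outdir``."""
    from pathlib import Path

    from .preprocess import write_expression, write_metadata

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    expr, meta, truth = generate(cfg)
    paths = {
        "expression": str(out / "expression.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "truth": str(out / "truth.tsv"),
        "config": str(out / "generator_config.yaml"),
    }
    write_expression(expr, paths["expression"])
    write_metadata(meta, paths["metadata"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    cfg.to_yaml(paths["config"])
    return paths
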