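# Methods

## The analysis model

`devstab` treats two quantities as the objects of inference:

* **developmental stability** of a phenotype — how little it varies when
  genotype and environment are held fixed. Operationally: expression
  differences between sex-matched inbred sibling embryos raised together.
* **evolutionary diversity** — how much the same phenotype varies across
  genetically heterogeneous individuals. Operationally: expression
  differences among hybrid descendants (all pairs) or between individuals
  of two separated wild populations (sex-matched cross pairs).

Both are measured at two resolutions: per gene (average absolute
log-expression difference over a pair design) and per stage (the
population variance V^ik of per-gene differences across the whole
transcriptome, one value per embryo pair). The scientific question the
pipeline addresses is whether stability predicts diversity — per gene via
Spearman correlation of the corrected statistics, per stage via rank-based
comparison of V^ik distributions across stages.

All computations use `log10(TPM + 1)`. TPM is a within-sample relative
measure; the log transform makes expression differences approximately
scale-free, and the +1 keeps zeros finite. Upstream read processing
(trimming, alignment, quantification) is out of scope: the pipeline
consumes TPM tables and a design sheet.

## Gene filtering

1. **Detection filter.** A gene is kept only if at least one individual in
   the dataset reaches `x >= 0.1` (configurable in [0, 1.5]). The filter is
   applied per dataset (per stage and group); statistics that compare two
   datasets use the intersection of the surviving gene sets, since both
   sides must be defined.
2. **Technical-error filter.** Per gene, sibling-pair differences are
   compared against technical-replicate differences with a one-sided
   rank-sum test (α = 0.01, "sibling differences stochastically larger").
   With four replicates of one condition the technical side has the six
   pairwise combinations. The alternative "averaged" mode (one mean error
   value per replicated condition) is available for designs with several
   replicated conditions, but is degenerate — a single value per gene —
   with only one condition per stage, so the pairwise mode is the default.
3. **Differential-mean selection (opt-in).** A two-sided rank-sum test per
   gene between the founder and descendant individuals' expression values,
   selecting genes whose mean level changed. Selecting *changed* genes
   before a conservation analysis conditions the gene set on the outcome
   variable (genes with noisier descendant expression are more likely to
   show an apparent mean shift at n = 5–6), so the pipeline defaults to
   skipping this step; `apply_differential_mean_filter=True` enables it.

The rank-sum engine uses midranks throughout. P-values are exact —
obtained from a subset-sum dynamic program over doubled midranks, which is
valid under ties — whenever the pooled sample size is ≤ 40; larger designs
use the normal approximation with tie correction and continuity
correction. The 13-to-25-vs-6 sibling/technical designs are therefore
always exact; for 13 vs 6 the largest achievable exact level below α =
0.01 is 0.0084, so the filter's realised type-I error sits just below its
nominal level (the calibration test asserts the 99% binomial interval).

## Running-median correction

The magnitude of `|x^i − x^k|` depends strongly on a gene's mean
expression. Genes are sorted by mean expression over the individuals in
the pair design (ties broken by gene id for determinism), and the median
raw statistic in a window of ±250 neighbours (window 501) is subtracted.
Within the top/bottom 250 ranks the window shrinks to the largest
symmetric half-width, so every window has odd length and no even-median
convention is needed. Corrected values are signed; zero means "typical
variation for this expression level".

## Stage statistic and inference

`V^ik` uses divisor **N** (population variance), not N−1, matching the
definition of the statistic as the realised spread of the observed
differences. The gene set entering V^ik is the stage's detection-filtered,
technical-error-passing set; founders and descendants each use their own
set by default (`common_gene_set=True` forces the intersection), and the
pipeline logs N per stage.

Stage comparisons: Kruskal–Wallis (tie-corrected, chi-square reference)
followed by Steel–Dwass. The Steel–Dwass implementation ranks only the two
groups being compared, standardises the Mann–Whitney statistic with the
tie-corrected variance, and refers `√2·|z|` to the studentized range
distribution with k groups and infinite degrees of freedom — the standard
large-sample form, matching common R implementations. A
`method="permutation"` variant refers |z| to a seeded Monte-Carlo null of
the maximum pairwise |z| under full relabeling; it is deterministic given
its inputs and noticeably more accurate for group sizes below ~30, where
the asymptotic form deviates from the exact familywise null by up to a few
percent in absolute p (quantified against a 20,000-permutation oracle in
the test suite). The asymptotic form remains the default because it is the
convention in the field's tooling.

One caveat the pipeline inherits from the design: V^ik values within a
stage share embryos (all-pairs designs) and share the stage's filtered
gene set, so they are not independent draws. The omnibus test is therefore
anti-conservative under the null; the stage-level conclusions should rest
on the effect sizes (median V^ik ratios) and the all-pairs contrasts, not
on the omnibus p alone.

## Synthetic data generator

`GeneratorConfig`/`generate` emulate the crossing design so every pipeline
stage is exercisable without downloads. On the log scale, individual
expression is `x_j = mu_j + s · sd_j · eps` with:

* `mu_j` — baseline log10 expression, gamma(2.2, 0.6) + 0.3 across genes
  (most genes between ~0.5 and ~3 log10 TPM);
* `s` — per-stage noise scale, defaults {15: 0.12, 23.5: 0.11, 28: 0.06,
  hatching: 0.13} (log10 units): realistic sibling-to-sibling biological
  variability with the hourglass minimum at the mid-embryonic stage;
* `sd_j` — per-gene factor, the **sum** of a mean-dependent floor
  (`0.1 + 0.4·Φ(z(mu_j))`, planting the monotone mean–variance dependence
  that the running-median correction is designed to remove — the additive
  floor is exactly what the correction subtracts) and a log-uniform
  per-gene factor spanning e^±2: the *stability* factor for founder
  embryos and, times an overall inflation of 1.3, the *diversity* factor
  for descendants and wild individuals.

The stability and diversity factors are linked by a Gaussian copula whose
latent correlation is chosen as `2·sin(π·rho_target/6)`, so their Spearman
correlation equals `rho_target` (default 0.4) exactly in distribution; the
truth record stores both factors per gene. The log-uniform marginal was
chosen over a log-normal deliberately: it spaces gene ranks evenly on the
log scale, which preserves the planted rank structure under estimation
noise far better (log-normal tails compress ranks and the small-sample
diversity estimate destroys them).

Technical replicates re-measure the first founder embryo of each stage
with sd 0.02 log10 units. Wild populations (all female, so that the
sex-matched cross-population product reproduces the published pair
counts) reuse the descendant noise factors plus a per-gene between-
population mean offset (sd 0.03). 8% of genes are below-detection
everywhere (flat values under the 0.1 cutoff). A `heavy_tails` flag swaps
the Gaussian noise for a variance-matched t(5).

What the generator does **not** emulate: count-level sampling noise and
its mean dependence at the low end, correlated gene modules, batch
effects, compositional (TPM renormalisation) coupling between genes,
sex-specific expression, or genuine segregating genetic architecture in
the descendants (diversity is a per-gene variance inflation, not allele
effects). Passing tests therefore demonstrate that the statistical
machinery recovers planted structure of the assumed form, not that the
biological conclusions transfer to any particular real dataset.

## Planted-correlation recovery and its ceiling

With the study-scale design (13–25 sibling pairs; 5–6 descendant embryos
giving 10–15 non-independent pairs), the per-gene diversity estimate has a
relative error of ≈ 0.33 (the Gini-mean-difference of six normal draws).
This caps the rank correlation between estimated and true diversity at
≈ 0.9, and the measured founder-vs-descendant Spearman rho at roughly
0.75–0.8 of the planted value (≈ 0.30 measured for a planted 0.4; the
recovery test in the suite documents the measured values). This is an
information bound of the design, not an implementation artefact — the same
attenuation applies to real data, meaning observed correlations understate
the true stability–diversity association at these sample sizes.

The wild-comparison correlation on generator output is high (≈ 0.8–0.9)
because descendants and wild individuals share the same per-gene diversity
factor by construction; real data, where the two diversities are only
partially coupled, give lower values.

## Numerical and determinism choices

* Exact rank-sum p-values: survival function of a subset-sum DP over
  doubled midranks; untied nulls cached per (n, m).
* Sorting for the correction is a stable lexsort on (mean expression,
  gene id); all written tables use a fixed float format (`%.10g`), so
  identical inputs and configuration produce byte-identical outputs.
* A fixed generator seed reproduces matrices, metadata and truth records
  exactly; the CLI `verify` subcommand re-derives every reported headline
  number from the serialized intermediates and fails on any mismatch.
* Degenerate inputs raise informative errors rather than silently
  degrading: self-pairs, duplicate ids, constant vectors in the
  correlation, groups smaller than two, even or tiny correction windows.

## Problem sizes used in the test suite

Unit tests run on hundreds of genes; the end-to-end property tests use the
default 10,000-gene configuration with the study-scale design (20 seeds
for correlation recovery, 100 replicates for hourglass recovery), keeping
the full suite within a few minutes on one core.
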