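# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `screversal`, in the order the pipeline runs them.

## Study design assumed

Three (optionally four) experimental groups — `young`, `aged`, `treated`
(drug-treated aged), optionally `vehicle` (vehicle-treated aged) — with a
small number of animals per group (default 3) and multiple cell types per
animal. All group comparisons are cross-sectional contrasts of cells:
`aging` = aged vs young, `treatment` = treated vs aged, `replicate` =
treated vs vehicle. Cells are treated as the unit of analysis; per-animal
random effects are *not* modeled (see Limitations).

## Synthetic data generator

The generator is a first-class module, not a test fixture: it defines the
conditions under which the statistical machinery is validated.

Per gene g: baseline log abundance m_g ~ Normal(`baseline_meanlog`,
`baseline_sdlog`) (defaults 1.0, 1.0); NB size θ_g ~ LogNormal(
`theta_meanlog` = 1.0, `theta_sdlog` = 0.5), so typical dispersions sit in
the 1–10 range observed in droplet data. Per cell c: library size L_c ~
LogNormal(8.0, 0.3) (median ≈ 3 000 UMIs, the order of a 10x v3 run).

Effects, all on the natural-log scale:

* Aging: in each cell type, a fraction `f_de` (default 0.10) of the
  non-special genes receive δ with Rademacher sign and |δ| ~
  Normal(0.6, 0.2) truncated at 0. The magnitude default is deliberately on
  the large side of what aging studies report — these are power-oriented
  defaults chosen once for recoverability at desk scale, since no
  effect-size distribution is available for the real data.
* Reversal: a fraction `p_rev` (default 0.9) of each type's aging-DE genes
  receive τ = −ρ·δ exactly; the rest have τ = 0. ρ (`rho`, in [0, 1.5]) may
  be scalar or per-cell-type, so one dataset can carry a reversed type and
  a ρ = 0 control type. Treatment-only effects (fraction `f_treat_only`,
  default 0) draw independent τ from the same magnitude family.
* Disease signature: `signature_size` genes (default 50) in one designated
  cell type get δ = `signature_shift_ln` (default 0.5) and τ = −ρ·δ —
  up with age, partially reversed by treatment.
* Markers: `marker_genes_per_type` genes (default 20) per type are elevated
  by `marker_boost_ln` (default ln 5) in their type.
* Mitochondrial genes carry the `mt-` prefix, a baseline boost (ln 10, so
  they hold a realistic few percent of counts), and a fraction
  `f_high_mito_cells` of cells has mito mass rescaled to an expected 30%
  share — these are the QC-failing cells.
* Mouse-to-mouse variation: per-sample, per-gene Normal(0,
  `sample_noise_sd` = 0.05) log jitter shared by all cells of that sample.

Counts: within each cell the relative expression w_g = exp(m_g + effects +
jitter) is renormalized to q_g = w_g/Σw, and counts ~ NB(mean = L_c·q_g,
size = θ_g) via a Gamma–Poisson draw. Renormalization makes library size
independent of group, so composition effects (boosting some genes slightly
deflates measured fold changes of all others) are present in the data, as
they are in real CP10K-normalized counts. One integer seed drives a single
RNG stream; identical config + seed is bit-identical.

`expected_reversal` computes the truth-level oracle: OLS slope of τ on δ
and the sign-discordance proportion over genes carrying any effect, either
for the realized truth or Monte-Carlo averaged over redraws of the effect
structure. With the defaults the oracle slope is a blend of −ρ·p_rev
(stochastic DE genes) and −ρ (fixed-shift signature genes).

What the generator does **not** emulate: ambient RNA, doublets, batch
chemistry differences, spatial structure, gene–gene correlation beyond the
compositional constraint, and per-animal random effects of realistic
magnitude. Passing recovery tests therefore demonstrates correctness of the
estimators under a clean NB world, not robustness to every artifact of real
tissue data.

## Quality control and normalization

Gene filter first (detected in ≥ 5 cells, strict "fewer than"), on the raw
matrix; then cell QC: a cell is removed iff total UMI *or* detected genes
fall strictly below the 5th or strictly above the 95th percentile of all
cells pooled (numpy linear-interpolation percentiles — the common "type 7"
convention; rank-cutoff alternatives differ only at the boundary), or its
mitochondrial fraction exceeds 0.20, or it has zero counts. Filters run
once, in that order, and are not re-applied.

Default normalization is log1p of counts per 10 000. The optional
Pearson-residual normalization fits, per gene, a Poisson GLM of counts on
log10 library size, estimates the NB dispersion by method of moments,
pools dispersions by bin-median smoothing across 20 mean-expression bins
(genes detected in < 10 cells take the pooled value directly), and clips
residuals (y − μ)/√(μ + μ²/θ) at ±√n_cells. This is a deliberate
simplification of kernel-regularized NB regression normalization; the full
regularization is out of scope. Fold changes and scores always use the
log-CP10K values so the lnFC convention stays well defined.

HVG selection is variance-stabilizing: a lowess trend (span 0.3) of log10
variance on log10 mean predicts each gene's expected sd; the variance of
counts standardized by it (clipped at √n_cells) ranks genes, ties broken
by gene ID. Defaults: 3 000 HVGs.

## Embedding, graph, clustering, cell typing

PCA (default 30 components) is exact: HVG-restricted values are centered,
scaled to unit variance (standardized values clipped at ±10, then
re-centered), and decomposed by full SVD; component signs are fixed by
making the largest-magnitude loading positive. The SNN graph uses k = 20
Euclidean nearest neighbors in PC space (self included in the neighbor
set), Jaccard edge weights, pruning below 1/15 — the de facto standard
defaults, which the underlying study leaves unstated. Clustering is greedy
multi-level (Louvain-style) modularity optimization with a
resolution-scaled null model at resolution 1.4, seeded through the stage
seed so labels are deterministic.

Cluster annotation: expression is z-scored per gene across all cells; a
cluster's score for a marker set is the mean over its cells of the mean
marker z-score. The argmax set is assigned if its score exceeds
`z_threshold` = 0.5 (no number exists in the source workflow for "high
expression"; 0.5 separates planted markers cleanly and is exposed in
config). Clusters above threshold for ≥ 2 sets are excluded as mixed
(e.g. endothelial fragments on pericytes), as are clusters with no marker
signal. Subtype analyses reuse the same machinery on a cell-type subset
with subtype marker sets.

## Hurdle differential expression

For gene g with log-normalized values y over the cells of one cell type in
two groups, the two-part likelihood is

* detection: logistic regression of 1{y > 0} on the design,
* continuous: Gaussian regression of y on the design over detected cells,
  with ML (not REML) variance,

and the contrast is tested by the LRT chi-square 2·(ℓ_full − ℓ_reduced)
summed over both parts, with df = number of parts in which the group term
is identifiable: 2 normally; 1 when detection is saturated (all or no
cells detected) or the continuous part is untestable (< 3 detected cells,
or a group with no detected cells); 0 ⇒ p = NA, excluded from the BH m
(setting p = 1 instead would deflate the q-values of testable genes).
For the default intercept + group design both parts have closed-form MLEs
(group detection rates; group means with pooled ML variance), which the
implementation uses vectorized across genes; the general path (e.g. with
the centered cellular-detection-rate covariate, off by default) runs Newton
IRLS with a 1e-8 ridge, flagging complete separation and refalling to a
stronger penalty. Empirical-Bayes variance shrinkage is deliberately
omitted — plain ML — and calibration is verified by simulation instead:
pooled type-I error ≈ 0.05 at nominal 0.05 on a pure NB null (the null
simulation carries no mouse jitter, since the model fits no random effect).

lnFC is the Seurat-v3 convention: ln(mean_A(e^y − 1) + 1) −
ln(mean_B(e^y − 1) + 1). The pseudocount compresses small fold changes at
low expression; since both contrasts are compressed alike, reversal slopes
are nearly unaffected. Genes are prefiltered to detection ≥ 0.1 in at
least one group (|lnFC| prefilter available, default off); both
prefilters are config-exposed and logged.

## Reversal statistics

The union of significant DEGs (q < 0.05 in either contrast) defines the
gene set; genes significant in one contrast but untested in the other are
excluded with a logged count (imputing lnFC = 0 would fabricate a
direction). A gene is reversed iff its two lnFCs have strictly opposite
signs; an exact zero is never reversed (zero carries no direction). The
regression is unweighted OLS with intercept of treatment lnFC on aging
lnFC (that axis order matches the scatter convention of
treated-vs-aging-change plots); slope inference is the standard t test.
Selection on significance and estimation noise attenuate the estimated
slope relative to −ρ·p_rev, which is why recovery is judged against the
truth-level oracle rather than ρ itself.

Top reversed genes: rank each contrast's *significant* DEGs by |lnFC|
(ties by gene ID); keep genes ranked ≤ 500 in both with opposite signs.
Ranking over all tested genes is available by flag. Consistency across
subtypes regresses, per subtype pair, the lnFCs over the union of their
significant DEGs (both directed slopes are reported; r² is shared).
Replication pairs the selected genes' lnFC in an independent contrast with
the aging lnFC and reports the fraction of opposite signs.

## Signature scores and group comparison

Module scores follow the binned-control scheme: genes are binned into 24
equal-size bins by average expression (ties by gene ID); for each
signature gene 100 controls are drawn from its bin without replacement
(with replacement if the bin is smaller), seeded; the score is mean
signature expression minus mean pooled-control expression per cell. The
bin/control counts mirror the common defaults of the reference scoring
function and are recorded in the output. Group comparison: tie-corrected
Kruskal–Wallis (all-tied data defined as H = 0, p = 1) and pairwise Dunn z
tests with tie correction, unadjusted by default (Holm optional).

## Over-representation analysis

One-sided hypergeometric tail of the query/set overlap within a universe,
BH across sets. The universe defaults to the genes tested in the relevant
DE contrast — a detected-gene background is the defensible default when
the original platform's background is unknown — and is always logged.
Depletion is not tested.

## Pipeline and determinism

One master seed; each stage derives its substream as
SHA-256(master:stage) mod 2³¹, so stages can be rerun in isolation.
Everything runs single-threaded; reruns with the same configuration are
byte-identical (floats serialize at 17 significant digits). The manifest
echoes the full configuration, library versions and per-stage counts, and
any stage failure leaves a `PARTIAL_OUTPUT` marker naming the stage.
Configuration is YAML with strict key checking: unknown keys abort with
the offending names.

## Problem sizes used in the checks

The packaged checks run at desk scale, chosen once for statistical power:
recovery and signature experiments use 1 000 genes, 2 (or 1) cell types,
3 samples/group × 80 cells — ≈ 240 cells per group per type; calibration
uses 2 000 genes at ≈ 200 vs 200 cells over three pooled replicates; the
demo is smaller still (700 genes, 50 cells/sample/type). At these sizes
the truth-level oracle slope is recovered within a few hundredths.

## Known limitations

* No per-animal random effect in the hurdle model and no pseudobulk path;
  with few animals per group and strong animal effects, cell-level tests
  overstate confidence. The generator's jitter default is small enough that
  calibration holds at the validated scale.
* The Pearson-residual normalization is a simplified NB regression, not a
  regularized one; it is not used for fold changes.
* Marker-based cluster annotation is a z-score rule, not a probabilistic
  assignment model; ambiguous clusters are dropped rather than resolved.
* The hypergeometric ORA treats genes as exchangeable; no gene-length or
  expression-level bias correction.
* UMAP visualization, trajectory inference, batch integration and doublet
  detection are out of scope.
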