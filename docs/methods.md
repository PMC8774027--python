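# Methods

`cytometa` re-implements, as a tested pipeline over synthetic data with
known ground truth, a cell-composition-aware meta-analysis of
case/control bulk brain transcriptomes: the kind of analysis used to
ask how much of the differential expression signal in a degenerating
tissue (such as the Parkinsonian substantia nigra) is genuine
transcriptional deregulation, and how much is an artifact of the
tissue's shifting cell-type composition.

## The generative model of the synthetic cohort

The generator (`cytometa.synthetic`) emulates a multi-study microarray
compendium. For sample *i* in study *j* and gene *g*:

    y_ig = log2( Σ_k p_ik · R_kg ) + b_jg + s_g·d·case_i + h·male_i·1[g ∈ sex genes] + ε_ig

- **Reference `R`** (cell types × genes, linear scale): every gene has a
  log-normal baseline (log2 mean 7, sd 1) modulated per cell type by a
  log2-normal factor with spread `celltype_sd = 2.0`. The spread makes a
  realistic fraction of genes strongly type-biased, which is what lets
  composition shifts masquerade as differential expression. Each of the
  `n_markers_per_type = 20` markers per type is forced to exceed its
  maximum across all other types by at least `marker_lfc = 3` log2 units
  (plus random headroom), mimicking strongly enriched panel markers.
- **Proportions `p_i`**: Dirichlet draws, per sample, so within-group
  heterogeneity exists. Control parameters (concentration ≈ 30) give
  mean proportions (NEU .40, ODC .30, AST .16, MIC .06, OPC .05,
  END .04); cases shift neurons down and oligodendrocytes up by about
  one pooled standard deviation each (SMD ≈ −1.05 / +1.05), with total
  concentration matched. The status-linked shift is deliberately
  confined to the NEU/ODC subspace — the two covariates the
  composition-aware model uses — so that correcting for them can, in
  principle, remove all composition-driven differential expression.
  This is a known idealization: in real tissue other compartments
  (e.g., endothelium) may also shift with disease, and any such shift
  outside the covariate subspace is uncorrectable by this model family.
  The non-shifting types still vary across samples and contribute
  composition noise.
- **Batch `b_jg`**: per-study per-gene offsets, N(0, `study_sd = 0.3`);
  exactly the structure a per-gene random study intercept absorbs.
- **Planted effects**: `n_true_degs = 30` genes (disjoint from markers
  and sex genes) receive a ±`deg_effect = 1.0` log2 status effect in all
  cell types; `gender_gene_count = 8` Y-linked-like genes get +2 log2 in
  males. Noise is i.i.d. N(0, `noise_sd = 0.5`).
- **Cohort structure**: nine studies with (control, case) group sizes
  (9,16), (7,9), (6,6), (15,11), (9,8), (5,6), (8,15), (5,8), (6,9) —
  70 controls and 88 cases in total. Gene count defaults to 2,000 for
  tractable simulation studies and is configurable upward.

Mixing happens on the linear scale; batch, condition, sex, and noise
effects are additive on the log2 scale, per microarray convention.
Randomness derives from one integer seed through keyed substreams, so
adding a study never perturbs earlier studies, and every stage is
bit-reproducible.

What the generator does **not** model: probe-level artifacts of
specific array platforms, RNA degradation, cell-size/RNA-content
differences between cell types, or platform-specific gene coverage
(matrices are complete by default; the pipeline itself handles missing
genes per study). Passing tests therefore demonstrate the statistical
machinery under a clean log-linear mixing model, not robustness to
those artifacts. Within-study variance components are plausible
placeholders, not estimates from any real cohort.

## Preprocessing

- **Probe collapse**: for genes measured by several probes the kept
  probe maximizes rank(variance) + rank(connectivity), where
  connectivity is the summed |Pearson r| with the gene's other probes.
  Rank ties keep the lexicographically smallest probe id
  (deterministic builds).
- **Quantile normalization** is missing-aware: each column's quantile
  function is computed on its observed genes only, the reference is the
  across-column mean quantile function on a common grid, and missing
  entries stay missing. With complete equal-length columns this reduces
  exactly to the classical mean-of-order-statistics scheme; ties
  receive the mean of the target values at their tied ranks.
- **Sex imputation**: 2-means clustering of samples on the top-75%
  most variable Y-linked genes; the cluster with lower mean Y
  expression is called female. Calls are flagged low-confidence when
  the cluster separation is under 10% of the pooled within-cluster sd
  (or the samples are indistinguishable, in which case a deterministic
  threshold rule is used instead of clustering).

## Marker-guided deconvolution

Proportions are estimated per study from marker panels alone (top 20
ranked markers per type present on the study's platform; a 2-gene
panel in the TH/SLC6A3 style stands in for dopaminergic neurons). The
estimator is an alternating non-negative least squares (NNLS) scheme
with three choices that matter:

1. **Inverse-mean weighting.** Noise that is additive on the log scale
   is multiplicative on the linear scale (variance ∝ mean²), so each
   marker row is divided by its across-sample mean before fitting.
   Without this, the few brightest markers dominate and accuracy
   roughly halves.
2. **Marker-sparse profile updates.** A marker's profile is
   re-estimated only in its own cell type; cross-type entries stay at a
   global baseline floor (the dimmest marker's mean). The marker
   assignment is the prior knowledge the method is built on; freeing
   all entries makes the factorization ill-posed at per-study sample
   sizes (10–30) and the iteration drifts toward uniform proportions.
   The unconstrained update is retained behind
   `constrain_profiles=False` for comparison.
3. **Abundance-scaled initialization.** A marker's mean bulk level
   confounds its type's abundance with its own brightness. Assuming
   marker brightness is exchangeable across panels, mean own-marker
   level per type estimates relative abundance; dividing it out places
   initial profiles on a common per-cell scale. Without this, rare
   types are systematically overestimated. This exchangeability
   assumption is also what ultimately pins the per-type scale — a
   limitation shared by any marker-only method, since the data alone
   cannot split `p·R` into its factors.

Proportions are projected to the simplex by sum-normalization at every
step; iteration stops when the largest proportion change is below
`tol = 1e-6` or after `max_iter = 100` rounds (a convergence flag is
returned). One consequence of the flat off-target floor: in the
degenerate noise-free case where a bulk profile *is* a pure cell-type
signature, about 1–2% of weight leaks to other types (own-type
proportion ≈ 0.98 rather than 1.0), because per-gene off-target levels
are not individually modeled. On realistic mixtures the estimator
reaches MAE ≈ 0.03 (flat Dirichlet, noise 0.1) and ≈ 0.05–0.07 on the
default cohort.

## Differential expression: two mixed models per gene

For each gene observed in ≥ 2 studies:

    unaware:  expr ~ status + gender + (1 | study)
    aware:    expr ~ status + NEU + ODC + gender + (1 | study)

Only two proportion estimates enter the aware model because simplex
proportions are strongly collinear (NEU and ODC are the dominant,
anticorrelated compartments); `proportion_correlations` reports the
estimate correlation matrix so the choice can be validated per
dataset. Constant covariates are dropped, which makes the two modes
agree exactly when NEU/ODC do not vary.

Models are fitted by REML with a single random intercept per study.
The solver (`cytometa.lmm`) exploits the block structure: all REML
quantities reduce to closed forms in per-study sufficient statistics,
the 1-D profiled criterion in λ = σ²_study/σ²_resid is minimized by a
coarse grid plus vectorized golden-section refinement, and thousands
of genes sharing a design matrix are fitted simultaneously. Inference
on the status coefficient uses a t-test with Satterthwaite
degrees of freedom obtained by finite differences of the closed
forms; boundary fits (σ²_study = 0) reduce to OLS with df = n − p, and
fits whose information matrix is not positive definite fall back to a
Wald z test, flagged per gene. The solver reproduces reference
mixed-model software (lmerTest) to ≥ 5 decimals on frozen fixtures,
including the Satterthwaite df.

DEGs are called at BH-adjusted p < 0.05 **and** |β_status| >
log2(1.2) (both strict), the fold-change reading consistent with model
coefficients on log2 data. BH runs per mode across all fitted genes.
A flag (`fc_from_means`) is not provided; the coefficient-based fold
change is the only implemented definition, since group-mean fold
changes conflate the composition effect the aware model removes.

## Proportion meta-analysis

Per study and cell type, an OLS model
`proportion ~ status + gender + age + braak` (covariates used only
where observed and non-constant) provides the status p-value, and
Hedges g — J·(mean_case − mean_ctrl)/s_pooled with J = 1 − 3/(4N − 9),
var = N/(n₁n₂) + g²/(2N) — feeds a DerSimonian–Laird random-effects
pool: τ² from the Q statistic by method of moments (REML pooling was
considered and not implemented; DL matches the common default of the
reference meta-analysis software and is exactly reproducible by hand).
BH correction runs across cell types. Calibration on null simulations
(identical Dirichlet parameters in both groups) keeps the 0.05-level
type-I error inside its exact binomial band; the default planted
neuronal shift (true SMD ≈ −1) is detected with the correct sign
essentially always at nine studies.

## Enrichment machinery

- **Preranked GSEA**: scores are −log10(adjusted p)·sign(β) (p floored
  at 1e-300), or betweenness centrality for network nodes. ES is the
  signed maximum deviation of the weighted running sum (hit weight
  |score|, exponent 1; miss decrement 1/(N − m)). The null permutes
  gene labels: random same-size sets, shared across sets of equal
  size; `n_perm = 100,000` by default. p is one-sided within the
  observed sign with a +1 pseudo-count; NES divides ES by the mean
  |null ES| of matching sign; BH across tested sets. Size filter
  15–500 after restriction to ranked items. An `exhaustive` mode
  enumerates all label sets for small problems and is tested against a
  brute-force running-sum oracle.
- **EWCE**: specificity s[t,g] = avg[t,g]/Σ_t' avg[t',g] from
  linear-scale per-type averages; the observed statistic is the mean
  specificity of the (deduplicated) gene list per type; the null is
  10,000 equal-sized gene sets sampled uniformly **without**
  replacement from all genes in the matrix (expression-matched
  sampling, used by later refinements of this test family, is out of
  scope and noted as a divergence). p is one-sided with a +1
  pseudo-count; z = (observed − boot mean)/boot sd. If the list equals
  the universe the null is degenerate: the result is flagged
  (`sd_zero`), z is NaN and p = 1.
- **Fisher enrichment**: one-sided hypergeometric upper tail with the
  conditional-MLE odds ratio. Backgrounds follow the two-universe
  convention: a protein-coding universe (default 20,000, configurable)
  for whole-network tests, the network size for central-protein tests.

## PPI network analysis

Edge lists are merged with symbols uppercased, optional human-symbol
allow-list, self-loops dropped, duplicate undirected edges collapsed
with source sets unioned, then degree-1 nodes removed in a **single
pass** (nodes whose degree drops to 1 during the pass survive); the
iterated 2-core variant is available behind a flag. Betweenness is
exact Brandes on the unweighted graph, unnormalized, per component.
Central nodes need degree **and** betweenness at or above the
nearest-rank 95th-percentile thresholds, ties included (tie inclusion
is what lets slightly more than 5% of nodes qualify); top-central
nodes additionally exclude DEG-encoded proteins.

## Numerical and degenerate-input choices

- Detection in single-cell data = value strictly > 0; marker log fold
  change = natural-log ratio of linear-scale means with a 1e-9
  pseudo-count (base configurable).
- Zero-variance studies are excluded from proportion-estimate
  correlations with a warning; groups with < 2 samples are excluded
  from Hedges g; genes observed in < 2 studies are skipped with a
  recorded reason.
- All simplex projections renormalize by the sum; all-zero NNLS weight
  vectors fall back to uniform.
- Golden-section REML refinement runs in log-λ to bracket width
  1e-10; λ below 2e-10 is treated as the boundary.

## Problem sizes of the shipped studies

The confounding-collapse study runs 20 replicates of the full default
cohort (2,000 genes × 158 samples, both models); the deconvolution
benchmark uses 50 flat-Dirichlet mixtures; meta-analysis calibration
uses 200 null + 100 planted proportion-only replicates on a light
150-gene configuration; EWCE calibration uses 500 random lists. These
sizes give stable aggregates while keeping the full validation run in
the low minutes on one CPU; all scale up by configuration.
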