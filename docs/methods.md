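# Methods

This note documents the statistical procedures pulpatlas implements, the
parameter defaults and why they were chosen, what the synthetic generator
does and does not emulate, and the numerical conventions that matter for
reproducibility.

## Data model and preprocessing

Counts are held as a sparse cells × genes integer matrix; on disk the
matrix travels as Matrix Market coordinate format stored genes × cells
(the common exchange convention) with the orientation recorded in a
sidecar JSON. Gene symbols are case-sensitive exact strings — no alias
resolution. Cells with zero total count are an error rather than silently
dropped: quality-control filtering (mitochondrial content, doublets,
size filters) is out of scope, so inputs are expected pre-filtered.

**Log-normalization.** `lognorm[c,g] = ln(1 + s · x[c,g] / t[c])` with
scale factor `s = 10 000` (the standard library-size target) and `t[c]`
the cell's total count. The inverse transform `expm1` sums to `s` per
cell to within 1e-6 relative — a checked invariant.

**Highly variable genes.** The Methods-level description "variance-
stabilizing transformation" leaves the implementation open; we use the
standardized-variance scheme: fit a degree-2 polynomial of
log10(variance) on log10(mean) over genes with positive mean (raw
counts), standardize each count against the trend-predicted standard
deviation, clip standardized values at √n_cells, and rank genes by the
variance of the clipped values. Ties break by gene id so selection is
deterministic. Default `n_hvg = 1000`, the size commonly used for
cross-object program correlations.

## Gene-set scoring

**Module score.** Genes are placed into 25 equal-frequency bins of mean
log-normalized expression; for each set gene, 100 control genes are
sampled from its bin (without replacement, falling back to with-
replacement when the bin is smaller; set genes are excluded from the
pool). The score is the per-cell mean over the set minus the mean over
the pooled controls. This is the standard control-binned scheme; bin
count and control count are configurable. The control draw is seeded
from the user seed *and the sorted set content*, so a given set scores
identically wherever it appears — this is what makes the specificity
contrast exactly antisymmetric under argument swap.

**Recovery-curve AUC.** Per cell, genes are ranked by log-normalized
expression, descending, ties broken by stable gene order (a deliberate
deviation from jitter-based tie-breaking: scores are deterministic).
With `K = ⌈threshold·G⌉` (default threshold 0.05) and `hits(k)` the
number of set genes among the top k, `AUC = Σ_{k≤K} hits(k) / Σ_{k≤K}
min(k,|S|)` ∈ [0,1], reaching 1 exactly when the set fills the top
ranks and 0 when no set gene enters the top K.

**Cluster summaries and specificity.** Scores are averaged per cluster;
z-scoring is applied *across clusters within a gene-set column* (an
sd-0 column becomes all zeros). Specificity contrasts are differences
of such z-scores; z-scoring per cluster mean rather than per cell was
chosen because the reported quantity is cluster-level. Cross-labeling
program correlation selects HVGs in each matrix (twice the requested
count), intersects them, truncates to `n_genes` by the sum of
within-matrix ranks, and computes Pearson r between cluster-mean
profiles; fewer than 50 shared features is an error.

**Condition tests.** Kruskal–Wallis across conditions, then all
pairwise two-sided Wilcoxon rank-sum tests BH-adjusted within each set.
The pairwise test uses the tie-corrected normal approximation *without*
continuity correction so that with two groups the identity
χ²₁(H) = z² holds and the KW and Wilcoxon p agree to numerical
precision.

## Differential expression and enrichment

Genes are pre-filtered to an expression fraction (share of cells with
count > 0) of at least 0.1 in either group; fold change is
`log2((mean_A expm1(lognorm)+1)/(mean_B expm1(lognorm)+1))` — means of
de-logged expression with a pseudocount of 1, the convention of the
widely used single-cell toolkits; reported rows additionally require
|log2FC| > 0.25. P-values: for `min(n_A,n_B) ≤ 10` the exact two-sided
rank-sum p is computed by a subset-sum dynamic program over doubled
mid-ranks (valid under ties), defined as `P(|S − E[S]| ≥ |S_obs −
E[S]|)`; otherwise the tie-corrected normal approximation *with*
continuity correction, which tracks the exact distribution to < 0.01
at the sizes where it is engaged. BH adjustment is applied across
tested genes.

Over-representation uses the upper-tail hypergeometric
`P(X ≥ k)` with the query/set overlap inside a finite universe
(default: all genes of the matrix, configurable — published analyses
rarely state their universe, so it must be explicit here), BH-adjusted
across sets. Volcano exports replace `p_adj = 0` by the smallest
positive double before the −log10.

## Ligand–receptor communication

The communication probability is a saturating mass-action form
`P = L·R/(Kh + L·R)` with `Kh = 0.5`. `L` and `R` are cluster-level
summaries of log-normalized ligand/receptor expression in the sender
and receiver cluster respectively: the Tukey trimean
`(Q1 + 2·median + Q3)/4` by default (linear-interpolation quantiles),
or the mean; multi-subunit complexes combine by geometric mean, so one
silent subunit silences the complex. The trimean vanishes unless a gene
is expressed in over a quarter of the cluster's cells, which acts as an
implicit expression-prevalence filter. This is a self-contained
reimplementation of the prevailing permutation-test design for
communication inference; it preserves the monotonicity and boundedness
the downstream summaries rely on but does not claim bit-compatibility
with any particular tool.

Within a condition, clusters with fewer than `min_cells = 5` cells are
excluded; the null relabels cluster assignments within the condition
`n_perm` times (default 100) and
`p = (1 + #{P_perm ≥ P_obs})/(1 + n_perm)` — the +1 correction keeps p
strictly positive so −log p stays finite. Significance at `alpha =
0.05`. Network summaries (counts and strength matrices, totals,
per-pathway strength) run over significant edges only; "total
interaction strength" over significant edges was chosen because the
cross-condition bar plots the pipeline emulates are computed from the
filtered interactions.

**Δ analyses.** Per-pair Δ tables sum significant-edge probabilities per
condition (aggregated over sender/receiver by default — the published
bar plots name only pairs — with a per-triple mode for chord exports),
report Δ = later − earlier, and rank most-decreasing first. The Δ
network takes the union of cluster universes, subtracts strength
matrices, and books per-node gained/lost significant edges counting both
roles (a gained self-edge contributes +2 to its cluster). Both gained
and lost edge sets are exported with signed weights.

**Bootstrap.** Cells are resampled with replacement within each
(cluster, condition) stratum at original size, so composition is held
fixed and only expression uncertainty propagates; the full inference
including the permutation test is recomputed per resample, and 95%
percentile CIs (2.5/97.5) are reported for the number of significant
interactions and the total strength, default `n_boot = 500`. The CI is
clamped to contain the point estimate (raw percentile intervals can
narrowly miss it in skewed small-n settings). Clustered duplicates make
resampled data slightly "lumpier" than the permutation null assumes, so
bootstrap replicates tend to find a few extra significant edges; the
CIs are accordingly asymmetric upward on the edge count — visible in
the examples and intrinsic to bootstrapping a permutation-filtered
statistic.

## Composition statistics

Subtype × condition counts are cross-tabulated with per-condition
proportions; Wald binomial CIs `p̂ ± z·√(p̂(1−p̂)/n)` are clipped to
[0,1] and degenerate at boundary proportions — retained because that is
the stated convention of the analyses being emulated (a Wilson option
exists but is not the default). The overall test is Pearson χ² with
zero rows/columns dropped. Pairwise contrasts build 2×2 tables (subtype
vs not-subtype across two conditions) and use the two-sided Fisher
exact test in the point-probability convention — the sum of
hypergeometric probabilities of margin-fixed tables at most as probable
as the observed one — evaluated in exact integer arithmetic: all tables
share the denominator C(N, n), so point probabilities are compared and
summed as integer numerators and divided once. This avoids the relative-
epsilon fudge float implementations need at probability ties. BH
adjustment pools all subtypes × all requested contrasts jointly. Odds
ratios use the Haldane–Anscombe +0.5 correction only when a zero cell
exists, with Wald log-scale CIs on the (corrected) cells; stars follow
the printed thresholds (*, **, *** at adjusted p < 0.05, 0.01, 0.001).
Δ-proportion matrices report percentage points, numerator minus
denominator condition, joined with the stars.

## Synthetic atlas generator

Counts follow `NB(mean = L_c · m[k(c), g, cond(c)], size = r)` with a
shared dispersion `r = 2` (variance = μ + μ²/2, a mid-range scRNA-seq
overdispersion) and per-cell library factors `L_c ~ LogNormal(0, σ)`
normalized analytically to mean 1, `σ = 0.3` by default. The mean
matrix starts from per-gene baselines drawn LogNormal(−1.5, 1) (median
≈ 0.22 counts, a realistic UMI depth given ~10³ genes), multiplied by
`2^log2FC` for a cluster's planted markers and by the condition's
activity multiplier for ligand genes in the sender cluster and receptor
genes in the receiver cluster of each planted edge. Cells are assigned
to clusters by a per-condition multinomial draw over the planted
proportions (so composition tests see genuine sampling noise); a
fixed-count mode apportions cells by largest remainder for
deterministic composition tests. Everything is a pure function of the
config seed. Builder conveniences pin marker or ligand/receptor
baseline means (default 0.5 for LR genes) so planted effect sizes are
controlled rather than confounded with the baseline lottery.

The `GroundTruth` record carries the planted markers, proportions, LR
program, and the analytic mean matrix, plus
`expected_lognorm_means()`: the exact numerical expectation
`E[ln(1 + s·X/T)]` under the NB law, integrating the library factor by
Gauss–Hermite quadrature and approximating the per-cell total `T` by
its conditional mean (it concentrates over hundreds to thousands of
genes; the residual bias is ≈ 1% at 300 genes and shrinks with gene
count). This is what lets bootstrap CIs be checked for *coverage of a
truth* rather than merely for shape.

**What the generator does not emulate:** batch effects, ambient RNA,
doublets, zero inflation beyond NB zeros, trajectory structure, or
gene–gene correlation beyond the planted programs. Passing
parameter-recovery tests therefore demonstrates correctness of the
statistics under a clean generative model, not robustness to the
artefacts of real dissociation and sequencing.

## Reproducibility and problem sizes

All randomness flows from one root seed through named substreams (a
hash of the stage name), so pipeline stages can be rerun independently
yet reproducibly, and two runs with the same seed produce identical
summaries. The validation suite and `scripts/acceptance.py` use
deliberately modest problem sizes chosen to estimate each quantity with
adequate precision on a single CPU: the permutation-calibration run
uses 10 clusters × 1000 cells × 50 pairs × 200 permutations (15 000
edge tests); recovery experiments use 100 independent simulations of
1000–2000 cells; bootstrap coverage uses 100 replicates of a
two-cluster, 300-cell design at `n_boot = 200` with the mean estimator
(whose population value the analytic truth computes directly); the demo
atlas uses 700 cells per condition, 8 clusters, and 30 pairs of which
twelve are active in Healthy, six collapsing at Early and six declining
gradually — which is what makes the significant-edge count and total
strength fall monotonically across conditions.

## Known limitations

- The communication probability is a reimplementation with documented
  defaults, not a clone of any released tool; absolute probabilities
  should be compared only within this package.
- Wald intervals are degenerate at boundary proportions (k = 0 or n).
- The bootstrap treats cluster labels as fixed; no re-clustering occurs
  inside resamples, so label uncertainty is not propagated.
- Exact Fisher enumeration is exact for any table size but slows for
  minimum margins in the many thousands.
- The pairwise-Wilcoxon BH family is per gene set, and the Fisher BH
  family pools all subtypes × contrasts; analyses that adjust within
  other families will differ.
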