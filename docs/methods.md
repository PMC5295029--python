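# Methods

This note documents the statistical models implemented in `mirgenet`,
the defaults and why they were chosen, what the synthetic-data
generator does and does not emulate, and the numerical conventions that
make every run reproducible.

## Setting and notation

Two log2 expression matrices are measured on the same n samples: miRNAs
`X` (n × p) and genes `Z` (n × q), with a binary outcome label per
sample. Throughout, the two class names are ordered alphabetically and
the first is "class0": a positive log2 fold change or a positive
direction tag means *higher in class0*. Sample sizes of interest are
small and unbalanced (the default design is 14 vs 26); all methods are
chosen to behave sensibly in that regime.

## Detection filter

A miRNA is kept iff it is detected in at least `⌈fraction · n⌉` samples
(default fraction 0.10, so 4 of 40). The ceiling-with-`≥` rule makes
"at least 10%" inclusive: exactly 10% passes. The filter is idempotent
and order-preserving. Detection flags are taken as given; the package
does not re-derive them from intensities.

## Sparse PLS discriminant analysis

The outcome is coded as a centered dummy matrix Y (one column per
class). Per component, a NIPALS power iteration alternates

1. `w ∝ Xᵀ Y v`, truncated to its `keepX` largest |entries| and
   renormalized to unit length,
2. `t = X w`, `v ∝ Yᵀ t`,

to convergence (‖Δw‖ < 1e-6, ≤ 500 iterations), followed by
regression-mode deflation of both X and Y on `t`. Hard truncation makes
"number of variables per component" an exact, interpretable knob;
ties at the truncation boundary break by feature index and the weight
sign is fixed by making the largest-magnitude entry positive, so fits
are deterministic. With `keepX = p` the first weight vector coincides
with the leading left singular vector of `X_cᵀ Y_c` (dense PLS-DA);
successive scores are orthogonal. Features are centered and scaled to
unit variance internally — the conventional scaling for this family of
methods even on a common log2 scale.

Explained variance per component is the drop in squared Frobenius norm
of the (scaled) X residual, `‖t‖²‖p_load‖² / ‖X₀‖²`.

Prediction uses the max-distance rule: regression coefficients
`B = W (Pᵀ W)⁻¹ Dᵀ` map a train-scaled sample to predicted dummy
values; the argmax wins, ties breaking to the first class.

Tuning is sequential: for each dimension h = 1..max_ncomp, the `keepX`
grid (default 1..50) is searched with earlier components frozen,
scoring the overall misclassification rate under stratified 10-fold CV
(the overall rather than class-balanced rate is reported because a
single error rate is the convention here; with 14 vs 26 samples the
majority class dominates it, which users should keep in mind). Ties
prefer smaller `keepX`, then fewer components. On easy problems this
legitimately returns very sparse models — CV error bottoms out early —
so parsimony, not signal recovery, is what the tuner optimizes.

## Random-variance t-test

Per feature, the pooled two-sample variance `s²` (d = n − 2 degrees of
freedom) is shrunk toward an inverse-gamma prior fitted across all
features. With `1/σ² ~ Gamma(a, rate r)` the posterior point estimate
is

    s̃² = (d·s² + 2r) / (d + 2a),     t = Δmean / (s̃ √(1/n₁ + 1/n₂)),

referred to a t distribution with `d + 2a` degrees of freedom. The
prior is fitted in closed form by method of moments on `log s²`, using

    E[log s²]   = log r − ψ(a) + ψ(d/2) − log(d/2)
    Var[log s²] = ψ′(a) + ψ′(d/2)

(ψ, ψ′ digamma/trigamma): `a` solves the strictly monotone trigamma
equation by bracketed root finding, `r` follows from the mean equation.
When the observed spread of log variances is not larger than the
chi-square sampling spread the moment equations have no solution; the
prior weight is set to zero and the statistic falls back to the
ordinary pooled t-test with a warning. As `a → 0` the shrunken t
reduces to the pooled t exactly.

BH q-values use the standard step-up (via statsmodels), reported in the
input order. The fold-change filter keeps `q ≤ 0.15` and
`|log2FC| > 1` — the fold-change inequality is strict, so the boundary
value is excluded. The global permutation test permutes class labels,
re-runs the full test + FDR per permutation, and reports the add-one
p-value for the observed count of significant features. On data with
no true signal the observed count is usually zero, in which case the
test returns p = 1 (with a warning): its null p-value is valid but
conservative by construction, which is the correct behavior for a
count-based permutation statistic with heavy ties.

## Trait GSEA

Genes are ranked by Pearson correlation with a continuous per-sample
trait — in the pipeline, an sPLS-DA component score — with ties broken
by gene identifier and constant genes assigned r = 0. The enrichment
score is the signed extremum of the weighted Kolmogorov–Smirnov
running sum: hits advance by `|r|^w / Σ_hits |r|^w`, misses retreat by
`1/(N − N_hits)`. The weight exponent defaults to 1 (the standard
weighted statistic). Significance comes from phenotype permutation: the
trait vector (not the class labels) is permuted, the entire ranking is
recomputed, and nominal p and NES use same-sign permuted scores with
the add-one convention; FDR q follows the usual pooled-NES procedure
capped at 1. Set-size limits default to [10, 500] after intersection
with the expression matrix; analyses of the synthetic cohort lower
`min_size` to 5 because the planted target block has five genes. The
bubble-plot axes are emitted as columns: z = (n_up − n_down)/√n and the
nominal p for −log10 transformation downstream.

Because all sets share each permutation's ranking, per-run significance
fractions have high variance across traits even under the null; the
test suite therefore calibrates nominal p by pooling sets across
independent traits.

## Regularized CCA

Within-block covariances are ridged, `Cov(X) + λ₁I` and `Cov(Z) + λ₂I`,
and the canonical system is solved through the SVD of
`(Cxx+λ₁I)^(−1/2) Cxz (Czz+λ₂I)^(−1/2)`. Weights are rescaled so each
variate has unit sample variance; the reported canonical correlations
are the empirical Pearson correlations of the paired variates, which
equal the singular values exactly at λ = 0 (verified against a direct
generalized-eigenvalue oracle). λ = 0 with a singular covariance (p > n)
raises with advice to use a positive penalty.

The penalties are tuned by k-fold CV on a grid — default 100 points
strictly inside (0.001, 0.05) for λ₁ and (0.0001, 0.05) for λ₂,
mirroring the open tuning region convention — scoring each cell by the
mean held-out correlation of the first variate pair under training-fold
weights (dimension 1 only: the cheapest faithful score). Ties prefer
smaller penalties. Dimension choice is the gap rule: retain the
dimensions before the largest consecutive drop in canonical
correlations; an all-equal or perfectly linear profile returns d = 1
with a "no clear gap" warning, and a manual override is honored and
logged.

Correlation-circle coordinates are each feature's Pearson correlations
with the *compromise variate* — the arithmetic mean of the X- and
Z-variates of a dimension (the natural symmetric choice when features
from both blocks share one plot). Only the first two dimensions are
used (`min(d, 2)`), and features with coordinate norm ≤ 0.3 are
dropped as irrelevant. The CIM similarity of miRNA i and gene j is the
inner product of their retained circle coordinates, bi-clustered with
Euclidean distance and average linkage.

## Target-network integration

Gene candidates are first restricted to the top 75% by across-sample
variance (ties at the cut go to the smaller identifier). Every
miRNA–gene pair among the retained features gets a Pearson correlation
and a one-sided test for negative correlation (the repression
hypothesis; a two-sided option exists), with BH correction over all
tested pairs — not per miRNA, a deliberate, configurable choice that
controls the FDR of the edge list as a whole. Prediction evidence is a
2-of-3 consensus over three target-prediction edge lists. The
integrated network is exactly the intersection: q < 0.1, r < 0, and
consensus support; isolated nodes are excluded. Hub statistics report
degrees (ties ranked by identifier), the edge coverage of the top-k
miRNAs, and genes co-targeted by at least m miRNAs. Edge identity is
exact string equality of (miRNA, gene); cross-database identifier
mapping is the caller's responsibility. A validated-interaction list,
when provided, only annotates edges and never filters.

## Network-smoothed SVM (stSVM)

The integrated network's nodes (default; a flag widens to all
rCCA-retained features with isolated nodes allowed) form an undirected,
unweighted graph with symmetric normalized Laplacian
`L̃ = I − D^(−1/2) A D^(−1/2)`; isolated nodes get a zero diagonal so
smoothing leaves them unmixed. The random-walk kernel is
`K = (aI − L̃)^steps`, positive semidefinite for `a ≥ 2` because the
normalized Laplacian spectrum lies in [0, 2]; defaults a = 2,
steps = 2. Raw node scores are the |t| of the random-variance test on
the combined miRNA+gene matrix, so both blocks share one scale.
Selection is a class-label permutation test on the *unscaled* smoothed
scores `K|t|` (rescaling to unit maximum is applied only for
reporting, since a per-permutation rescale would distort the null);
p-values use the add-one convention and features with p < 0.05 are
kept. With steps = 0 the kernel is the identity and the procedure
reduces exactly to plain t-statistic permutation selection.

The signature is scored by a linear SVM (fixed C = 1, balanced class
weights for the 14/26 design) under 10-times-repeated stratified
10-fold CV. Decision values are pooled across folds within a repeat;
each repeat's AUC is the rank statistic of those pooled values
(equivalent to the pair-counting U statistic), and the reported ROC
curve pools decision values across repeats. Feature selection is not
redone inside the folds by default — this mirrors the conventional
wiring of the upstream analysis and means the AUC is optimistic
whenever selection saw the evaluation samples; a nested run (selection
inside a held-out loop) is the honest alternative and can be assembled
from the same primitives.

## Synthetic cohorts

The generator plants every structure the pipeline is meant to recover,
at the study's scale by default: 14 + 26 samples, 614 miRNAs, 2,000
genes, Gaussian log2 intensities (baselines N(8, 1.5²), noise SD 1).

* **Component 1** — 10 miRNAs shifted between classes by
  `effect_size` (default 2) within-class SDs: strong univariate
  discriminators.
* **Component 2** — 6 masked-contrast pairs `(u + s, u − s)`: a shared
  latent `u` with 10× the noise SD hides a class shift `s` carried by
  the contrast. The pair separates the classes sharply (standardized
  contrast effect ≈ 5) while each marginal's standardized shift is
  ≈ effect/20 — undetectable by per-feature tests at n = 40. Exact
  marginal nullity is impossible when the joint separation is a mean
  shift, so "masked" is the honest implementable version of
  "multivariate-only".
* **Targets** — 3 regulator miRNAs (members of component 1) jointly
  repress 5 genes: `gene = baseline − slope · mean(parents) + noise`.
  Co-targeting (every regulator hits every target, 15 edges) is the
  default topology, matching the hub structure typical of real
  miRNA–target networks; a single-parent mode exists, under which the
  noiseless limit gives r → −1 per edge. A separate `target_noise_sd`
  lets the repression residual shrink independently of the global
  noise level.
* **Gene sets** — one truly enriched set (the 5 targets) plus 20
  size-matched random sets, so enrichment FDR behavior is testable.
* **Databases** — three edge lists containing each true edge with
  probability TPR (0.8, 0.8, 0.8) and each random non-edge with
  probability FPR (0.02, 0.02, 0.02); a true edge then survives the
  2-of-3 consensus with probability 3·TPR²(1−TPR) + TPR³ ≈ 0.896.
* **Detection** — 10 miRNAs are planted with a 2% detection rate to
  exercise the detection filter.

What the generator does **not** emulate: probe-level microarray noise,
batch effects, FFPE degradation, heavy-tailed intensities, correlated
null genes, or identifier mismatches between databases. Passing the
recovery tests therefore demonstrates that the chain is correctly
wired and statistically calibrated under its own assumptions — not
that it would perform identically on real arrays.

At the default effect size 2 the weakest planted component-1 miRNA
trades places with the maximum of ~600 null features in roughly 15% of
cohorts — an order-statistics fact worth knowing when interpreting
recovery rates near their thresholds.

## Pipeline, determinism, problem sizes

The pipeline runs stages in a fixed order (inputs → detection filter →
miRNA sPLS-DA → differential expression → GSEA → gene sPLS-DA → rCCA →
network → stSVM → report), each stage reading and writing plain
TSV/JSON in the run directory, so any stage can be re-run in isolation
from its serialized inputs. Per-stage seeds derive from the single
global seed via `SeedSequence((seed, stage_index))`. Floats are
serialized with a fixed format and JSON keys are sorted; no timestamps
are written, so identical config + seed yields byte-identical bundles.
Configuration is one YAML document whose defaults are the parameters
quoted throughout this note; stage errors abort with the stage name and
a machine-readable code (`validation_error` vs `computation_error`,
CLI exit codes 2 and 3).

Validation and benchmark runs use deliberately scaled search spaces —
the recovery benchmark fits sPLS-DA at the planted sparsity, tunes rCCA
on a 6×6 grid with 5-fold CV, uses 500 selection permutations and
10×10-fold CV per cohort; test-suite pipeline runs use reduced keepX
grids and permutation counts. These are the package's own problem-size
choices for routine verification; all defaults remain the full-size
parameters.

## Known limitations

* Non-nested stSVM evaluation (above) inflates AUC relative to a fully
  nested protocol.
* The GSEA FDR uses the pooled-NES procedure, which is noticeably
  conservative with few, equally-sized gene sets.
* The rCCA CV score uses only the first variate pair; when the shared
  structure is genuinely multi-dimensional the tuned penalties may be
  suboptimal for later dimensions.
* The empirical canonical correlations of regularized variates are not
  guaranteed monotone non-increasing for λ > 0 (the regularized
  singular values are; both are exposed on the model).
* `ClassLabels` insists on exactly two classes; multi-class extensions
  of the dummy coding are not implemented.
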