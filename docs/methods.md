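# Methods

This note records the statistical models, the tunable parameters and the
design choices behind `specsel`, including what the synthetic-data
generator does and does not emulate.

## Count model and the beta-binomial test

Spectral counts are treated as draws of `y_ij` successes out of `T_j`
trials, where `T_j` is run *j*'s total spectral count (recomputed after
low-count filtering; a configuration switch allows pre-filter totals).
The beta-binomial parameterization is `α = π/θ`, `β = (1−π)/θ`, so the
intra-run correlation is `θ/(1+θ)` and `θ → 0` degenerates to binomial
sampling.  The null model fits one shared `π` and one `θ`; the
alternative fits class-specific `π_g` with a shared `θ`.

Fitting maximizes the likelihood kernel (the binomial coefficient is
constant in the parameters and cancels from every likelihood ratio) over
`(logit π, log θ)` by L-BFGS-B with analytic digamma gradients, from two
starts (per-class pooled proportions; the null optimum replicated across
classes, which guarantees `ℓ_alt ≥ ℓ_null` up to optimizer tolerance).
The `θ = 0` boundary is evaluated separately with its closed-form pooled
MLEs and the better of interior/boundary wins.  `Λ` is floored at zero
and referred to `χ²_{G−1}`.  The optimizer was cross-checked against an
independent coarse-to-fine grid search; agreement is ~1e−4 in `Λ`.

Calibration: on simulated global nulls the test holds its nominal 5%
level for well-observed proteins (per-protein totals above ~100 spectra)
and is conservative below that — with totals of a few spectra spread
over 18 runs the `χ²` reference overstates the achievable evidence, so
rejection rates fall toward zero rather than inflating.  Conservatism,
not anti-conservatism, is the failure mode.  No multiple-testing
correction is applied by default (selection is at raw p < 0.05, with
Benjamini-Hochberg available to callers via the returned p-values).

The one-way ANOVA baseline runs on raw counts (the classical approach it
stands in for operated on count tables directly); proteins with zero
within- and between-class variance get p = 1 by convention, zero within-
with nonzero between-class variance gives p = 0.

## Nearest shrunken centroids

`d_ik = (x̄_ik − x̄_i)/(m_k (s_i + s_0))` with pooled within-class
standard deviation `s_i`, offset `s_0 = median(s_i)`, and
`m_k = sqrt(1/n_k − 1/n)` (the variance factor of `x̄_ik − x̄_i` when
the overall mean includes class k; the `sqrt(1/n_k + 1/n)` convention
found in some descriptions is a config switch).  Soft-thresholding by Δ
gives `d'_ik`; shrunken centroids are `x̄'_ik = x̄_i + m_k (s_i+s_0)
d'_ik`; the discriminant is `δ_k(x) = Σ_i (x_i − x̄'_ik)²/(s_i+s_0)² −
2 log π_k` with class probabilities `∝ exp(−δ_k/2)`.  Priors default to
empirical class frequencies.  A feature with `s_i = 0` and `s_0 = 0`
has its `d_ik` defined as 0.  The Δ grid for tuning is 30 evenly spaced
values from 0 to `max|d_ik|` computed on the training fold.  Feature
ranking uses the unshrunken `max_k |d_ik|`, so the order is
Δ-independent; the selected set at a given Δ is the features with a
nonzero shrunken deviation.

## SVM-RFE

Classifiers are one-vs-one linear soft-margin machines (libsvm via
scikit-learn); multiclass prediction is pairwise voting with ties broken
by summed decision values.  Features are standardized with
training-fold statistics before every fit — squared weights are only
comparable on a common scale, and the elimination criterion is
`c_i = Σ_pairs w_i²`.  Elimination removes one feature per round once at
most 200 survive and 10% per round above that, bounding the number of
fits on ~1,700-feature matrices while keeping single-feature resolution
where optimal subsets live; ties in `c_i` drop the lexicographically
larger protein id first, which makes rankings deterministic and
independent of input feature order.  The cost C is tuned in the inner
CV loop over {0.01, 0.1, 1, 10, 100} by default; a fixed C is a config
choice.

## Double cross-validation

Outer loop: stratified 6-fold by default (one run per class held out
per fold at the 18-run design), leave-one-out available; every outer
training fold must contain all classes.  Inner loop: stratified 5-fold
on the outer-training set (automatically reduced if a class is too
small).  Inner records carry, per candidate tuning point, the subset
size, mean validation error and (for NSC) the summed probability
assigned to the true class.  Subset rules — SVM-RFE: smallest N at the
minimal mean error; NSC: minimal error, then maximal true-class
probability sum, then smallest N.  Outer-test samples are predicted
once with the tuned model; the pooled held-out predictions give the DCV
error, confusion matrix, accuracy and one-vs-rest
sensitivity/specificity.  The reported feature list comes from applying
the same inner-tuning procedure to the full data set and refitting; the
DCV error remains the performance estimate for that protocol.

Classifier features are per-run relative abundances `y_ij/T_j` by
default (raw counts and z-scores selectable).  Relative abundance is a
per-column operation and all standardization happens inside training
folds, so outer-test samples cannot influence tuning; this is verified
by a test that corrupts held-out columns and asserts identical inner
decisions.  All randomness flows from one seed recorded in the report,
and reports serialize deterministically (byte-identical across reruns).

Per-protein class association uses the standardized centroid deviation
`(x̄_ik − x̄_i)/(s_i + s_0)` on relative abundances: the protein joins
the class with the largest absolute deviation, direction up/down by its
sign, with a zero maximum flagged ambiguous.  One uniform rule serves
all three methods.

## List concordance

Jaccard `|A∩B|/|A∪B|` (two empty sets count as 1) over top-k prefixes,
reported as the mean over list pairs (a joint three-way variant is also
emitted); the Venn partition splits the union of the three optimal
subsets into the 7 exclusive regions.

## Clustering diagnostics

Heat-map clustering operates on z-scored rows under the Pearson distance
`d = 1 − r` (constant vectors sit at distance 1 from everything);
average linkage by default, with ids pre-sorted so residual ties are
resolved lexicographically.  Sample trees are built by neighbor joining
on Euclidean distances between runs in z-scored protein space.  The NJ
implementation joins the `Q`-minimizing pair with the standard
branch-length formulas; negative length estimates are clamped to zero
with the deficit moved to the sibling branch, preserving path lengths
through the new node, and `Q` ties break on lexicographically smallest
clade labels so the topology is independent of taxon input order.  For
additive inputs the tree reproduces the input distances exactly (tested
to 1e−9; cross-checked against an independent NJ implementation).
Silhouettes use `s(i) = (b−a)/max(a,b)` with the singleton-cluster
convention `s = 0`; the tree silhouette applies the same formula to
leaf-to-leaf path lengths, so it equals the data silhouette whenever the
distances are additive.  Z-scoring rows before sample distances keeps
high-abundance proteins from dominating; a constant row z-scores to
zeros, neutral under both distances.

## Synthetic data

The generator emulates a three-class, six-runs-per-class secretome
study: ~1,700 proteins (the post-filter scale of a ~2,500-protein
identification list), per-run totals uniform in [7,500, 9,500].
Baseline relative abundances are log-normal with σ = 2 — a heavy tail
in which a few proteins absorb most spectra, as in real shotgun data.
Planted proteins carry a multiplicative fold effect in one class,
abundances are renormalized per run, and counts are drawn either
multinomially (θ_sim = 0, column totals exact) or protein-wise from the
beta-binomial (overdispersed, totals approximate).

The default θ_sim = 0.001 was calibrated so that simulated
replicate-pair R² of counts (0.72–0.84) falls inside the reproducibility
range reported for real label-free replicates (R² 0.64–0.96); much
larger values (e.g. θ = 0.05, used deliberately in the null-calibration
stress test) destroy replicate correlation entirely and represent a
worst case rather than typical data.  `planted_spec` places effects only
on proteins quantifiable at baseline (expected ≥ 1 spectrum per run):
an effect planted on a protein the instrument essentially never samples
is undetectable in principle and would benchmark the sampler rather
than the selector.

What the generator does *not* emulate: peptide-level identification and
shared-peptide ambiguity, run-order or batch drift, abundance-dependent
overdispersion (θ is shared across proteins), and missingness beyond
sampling zeros.  Passing tests on these simulations therefore validate
the statistical machinery under the stated count model, not robustness
to identification artifacts.

Renormalization makes the data compositional: planting strong effects
on abundant proteins slightly depresses every other protein's relative
abundance in the affected class, so very abundant null proteins can show
small but real proportion differences.  This mirrors real spectral-count
data (totals are fixed by instrument time) and slightly inflates the
selected-set sizes in planted simulations.

## Numerical and degenerate-input conventions

- Low-count filter: protein kept iff aggregated count (total by
  default, max per run optional) strictly exceeds the threshold
  (default 2, i.e. "≤ 2 discarded"); idempotent; filtering everything
  warns rather than errors.
- Fold change: class means with zeros replaced by 1, signed so
  `|FC| ≥ 1` (negative = lower in target); regulation flag at
  `|FC| ≥ 1.3`.
- Optimizer tolerances: L-BFGS-B `ftol` 1e−13, `gtol` 1e−9; `log θ`
  bounded in [−16, 6]; logits clipped at 1e−14 to avoid saturation.
- Confusion metrics: a class absent from the true labels has undefined
  sensitivity, reported as NaN.

## Problem sizes used in the shipped experiments

The test-suite and acceptance-script experiments run at the design the
package targets: 1,700-protein matrices for the end-to-end recovery run,
1,000 proteins for null calibration, 50 random 6-taxon trees for NJ
exactness, and smaller (100-400 protein) matrices for the orchestration
and property tests, keeping the full suite within a few minutes on a
single CPU.
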