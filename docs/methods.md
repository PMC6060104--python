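# Methods

This note records the models implemented, the defaults chosen where the
design was genuinely open, and what the synthetic validation does and does
not establish.

## The metric

wSDM(x, y) = sw(X̂, Ŷ) · I(x, y), with both factors computed from the raw
series:

**Dependence factor I.** The default is Hoeffding's Phi-Square of the
empirical copula, `90 ∬ (C_n − Π)²`, where C_n is built from
pseudo-observations u_i = rank(x_i)/n (average ranks for ties). The
integral of the piecewise-constant C_n has an exact closed form in the
pairwise ranks:

    ∬ C_n²    = (1/n²) Σ_ij (1 − max(u_i,u_j)) (1 − max(v_i,v_j))
    ∬ C_n·uv  = (1/n)  Σ_i (1 − u_i²)(1 − v_i²) / 4
    ∬ (uv)²   = 1/9

so no numerical integration is involved; the tests verify the closed form
against an independent cell-by-cell integration oracle to < 1e−6 (observed
~1e−14). The constant 90 is the reciprocal of the population integral for
the comonotone copula (∬(min(u,v) − uv)² = 1/90, confirmed by numerical
quadrature), so perfect monotone dependence maps to 1.

Two alternatives are selectable: Schweizer–Wolff σ (12 ∬|C_n − Π|,
estimated by the Riemann sum over the n×n copula knots) and κ
(4 sup|C_n − Π|, the supremum evaluated over the knots). The knots are the
jump points of C_n; evaluating κ inside the right-open cells instead would
pick up a spurious O(1) deviation next to (1,1) at small n, which is why
the knot convention is used.

Finite-sample behaviour: with the rank/n convention the estimator is
biased upward near perfect dependence (countermonotone pairs overshoot 1
by ~4 % at n = 100, ~0.8 % at n = 1000) and downward at the comonotone
limit. `normalization="finite"` rescales by the comonotone value at the
same n, making monotone samples score exactly 1; the asymptotic constant
90 is the default because it keeps values comparable across series
lengths. A `scale="n+1"` pseudo-observation convention is available for
users who want the open unit square.

**Symbolic factor sw.** Each series is encoded over a two-symbol alphabet
— UP iff the next sample is strictly larger, else DOWN — giving n − 1
symbols; sw is 1 minus the normalized Hamming distance between the two
strings. Equal adjacent samples carry no local increase and encode DOWN by
default (`tie="up"` flips this); ties are measure-zero for continuous BOLD
data, so the rule is benign but documented. The linear Hamming complement
is the minimal mapping reproducing the stated [0, 1] endpoints. Wider
ordinal patterns (permutation-entropy style alphabets) are deliberately
out of scope: the two-symbol adjacent-pair transform is the defined
measure.

wSDM is symmetric, non-negative, bounded by the unweighted dependence, and
invariant under strictly increasing marginal transforms of either series
(bit-exact: the pseudo-observations and the symbols both depend only on
order). A joint reordering of both series leaves the copula factor
unchanged but rebalances which dynamics drive the symbols, which is the
mechanism behind the temporal-coherence weighting.

## Surrogate independence test

`independence_test` builds the null by reordering y's samples. Two nulls
are provided:

* `"shift"` (default): random circular time shifts. These preserve y's
  autocorrelation and are exactly distribution-preserving when y is
  circularly stationary — which the generator's DFT-band-limited signals
  are. Full permutation on band-limited signals is anti-conservative
  (observed rejection 0.26 at nominal 0.05 for wSDM), because the observed
  statistic reflects smooth series while the permuted null reflects white
  ones; the shift null restores nominal level (0.05–0.07 observed over 200
  replicates).
* `"permutation"`: full sample permutation, exact-level for exchangeable
  (white) data.

p-values use the add-one estimator (1 + #{null ≥ observed})/(B + 1).

## Seed maps and thresholding

Seed spheres are defined in world (mm) coordinates; a voxel belongs to a
sphere when its center lies within the radius. Bilateral centers are
pooled into one mean series (one map per network). The default radius is
6 mm — a literature-standard stand-in, configurable, not a fitted value.
Maps are thresholded proportionally: values strictly below the q-th
percentile of in-mask values are zeroed (values equal to the cutoff are
retained, making the operation idempotent and leaving all-constant maps
intact). The percentile is computed over in-mask voxels only, since
association values exist nowhere else. The 30th percentile is the
pipeline default.

## Group statistics

One-sample t-maps display a group's connectivity; family-wise correction
is Bonferroni over in-mask voxels by default, with a sign-flip max-T
permutation option (random-field-theory correction is intentionally not
implemented). Two-sample maps test controls > patients one-sided at
uncorrected p < 0.001. Both apply a cluster-extent filter (default 30
voxels, 26-connectivity). Zero-variance voxels get a capped t (sign ×
1e6) rather than ±inf. The reproducibility metric is the Spearman
correlation (Pearson selectable) of paired t-values over the joint
in-mask region of two sites' maps — all jointly in-mask voxels by
default, with a flag to restrict to suprathreshold ones — plus the OLS
slope of site-2 on site-1 t-values; slopes from two measures are compared
with t = (b₁ − b₂)/√(se₁² + se₂²) on n₁ + n₂ − 4 degrees of freedom.

## Classification

Features are in-mask voxel values; the threshold percentile doubles as
the feature-count hyperparameter (top (100 − q)% of voxels ranked by the
training-set mean map). Nested CV: stratified 5-fold outer, 4-fold inner,
inner folds select the percentile (ties to the lowest), the winner is
refit on the full outer-training set and scored once on the held-out
fold. Voxel selection and standardisation are fit on training subjects
only — the leakage probe in the test suite plants a per-fold sign-flipped
label artifact in outer-test folds and verifies accuracy stays at chance.
Classifiers: linear SVM (C = 1) and kNN (k = 5, Euclidean), both behind a
standardising pipeline and both configurable. Accuracy is reported as the
outer-fold mean and as pooled predictions; ROC/AUC come from pooled outer
decision scores. Measures are compared by a paired sign-flip permutation
test on per-fold accuracy differences (exhaustive up to 20 folds); with 5
outer folds the smallest attainable two-sided p is 1/16, so the
comparison is descriptive at the default fold count and sharpens with
more folds.

## Synthetic data

The generator emulates preprocessed resting-state BOLD: white noise
band-limited to 0.01–0.08 Hz at TR 2.5 s by zeroing DFT coefficients
(zero-phase, exactly zero out-of-band power, no ringing that would
imprint symbol structure), unit variance, ~200 volumes. Coupled pairs are
y = √(1 − s²)·e + s·f(x) with strength s ∈ [0, 1] and f ∈ {identity,
square, sin(πx), lag, none}; s = 0 gives exact independence. The
two-group "toy brain" plants a seed region sharing a latent source and a
disjoint target region coupled to f(source) with group-specific strength
— controls 0.8, patients 0.2 by default (the hypo-connectivity structure
expected of the salience network in bvFTD), 20 subjects per group at two
sites differing in noise scale (×1.3) and series length (200 vs 180
volumes) to emulate heterogeneous acquisition. Defaults follow the scale
of a modest two-center clinical study and are configurable.

What passing tests show — and what they do not: the generator produces
circularly stationary Gaussian fields with block-structured, noiseless
region geometry and no hemodynamic convolution, motion, or spatial
autocorrelation beyond the planted couplings. Results on it validate the
estimators, the calibration of the surrogate test under the stated
conditions, and the absence of leakage in the pipeline; they do not
establish effect sizes, accuracies, or reproducibility values for real
BOLD data.

## Problem sizes and numerical choices

The validation suite uses n = 200 samples per series, 200 replicates and
1000 surrogates for rejection rates, n = 1000 for the analytic limits,
and the default 20/20-subject toy brain (14×14×6 grid) for the pipeline;
these sizes give binomial error bars of ~±3 percentage points on rates
while keeping the full run in minutes on one CPU. Degenerate inputs are
rejected early (series shorter than 3, non-finite values, zero-variance
input to Pearson, empty seed–mask intersections, mismatched grids);
percentile 0 is the identity threshold; all-equal maps survive
thresholding via the ≥-cutoff rule. Every stochastic routine takes an
explicit seed or generator, and the pipeline writes a manifest (config,
seed, input checksums) from which its outputs are reproducible.
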