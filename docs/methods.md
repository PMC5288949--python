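# Methods

## Model

The selection criterion is the optimum of the multiple-kernel soft-margin SVM
dual. For samples x_i with labels y_i in {+1, -1} and a bank of M base
kernels K_m, the combined kernel is the convex combination
K = sum_m d_m K_m with d on the probability simplex, and

    W(a, d) = sum_i a_i - 1/2 sum_ij a_i a_j y_i y_j sum_m d_m K_m(x_i, x_j),
    J = min_d max_a W(a, d)   s.t.  sum_i a_i y_i = 0,  0 <= a_i <= C.

J is the margin-based difficulty of the problem in the best mixture of the
base kernels: small J means wide separation. Stage 1 ranks individual
features by their single-feature J (ascending); stage 2 grows a subset Z
greedily by the largest reduction dJ = J_prev - J_{Z+{f}}, stopping at
dJ <= 0, at |Z| = r_max, or when candidates are exhausted. Because dJ at an
empty subset (J_0 = +inf) orders candidates exactly like -J, round one
always picks the best single feature.

Assumptions inherited from the SVM: two classes only, kernels positive
semidefinite, every feature finite after preprocessing. The per-feature
criterion, like any univariate ranking, can miss features informative only
in combination; stage 2 partially compensates within the shortlist.

## Optimization

The inner problem at fixed d is a box-and-equality-constrained concave QP,
delegated to libsvm (precomputed-kernel mode, tolerance `qp_tol`, default
1e-8); the dual vector, objective and bias are reconstructed from the
returned support coefficients using the closed-form expressions, so reported
quantities do not depend on libsvm's internal bias convention. The bias
places the boundary midway between the extreme class scores:
b = -1/2 [max_{y=-1} f0(x_i) + min_{y=+1} f0(x_i)].

The outer descent on d uses the reduced gradient with the largest-weight
coordinate as reference. By Danskin's theorem dJ/dd_m at the inner optimum
is -1/2 a^T (y y^T o K_m) a; coordinates pinned at zero with outward
gradient stay fixed. The step starts at the largest simplex-feasible step
and Armijo-backtracks (factor 0.5, up to 20 halvings, sufficient-decrease
constant 1e-4). The loop stops when the relative change in J falls below
`dual_gap_tol` (default 1e-3) or after `max_outer_iter` (default 200)
iterations, in which case the model is flagged `converged=False` rather than
raising. J is non-increasing across outer iterations by construction; the
recorded `J_history` lets tests assert it directly. Weights start uniform
(1/M), making runs deterministic. With identical kernels in the bank the
weights are indeterminate; only the objective is meaningful there, and tests
assert only the objective in degenerate cases.

`sign(0)` in prediction maps to +1 — arbitrary but fixed.

## Kernels and standardization

Default bank: linear, RBF with denominator 2 (bandwidth parameter 1), and
the inhomogeneous quadratic polynomial with offset 1. The RBF denominator is
parameterized as `2 * rbf_bandwidth`, so the default reproduces
exp(-||u-v||^2 / 2).

Two numerical conditioning steps are on by default, each behind a flag:

* **Per-feature z-scoring** (statistics fit on training samples only).
  RBF distances are scale-sensitive; without standardization a
  high-variance feature dominates every distance. Exact-formula tests
  disable it.
* **Trace normalization of each base Gram to trace = n.** The three kernel
  families live on different scales (a quadratic kernel of z-scored data has
  entries orders of magnitude above an RBF kernel); without normalization the
  weight simplex would mostly encode scale, not information. The scaling
  factor is recorded on the Gram object and applied to cross-kernel blocks
  at prediction time.

Zero-variance features cannot be z-scored or trace-normalized; stage 1
assigns them J = +inf (ranked last, flagged) instead of failing, since
filtered expression matrices routinely contain constants. Constancy is
detected by exact zero range rather than by the standard deviation, which
floating-point rounding can leave slightly positive.

Stage 2 computes candidate Grams incrementally: the inner-product and
squared-distance matrices both decompose additively over features, so the
Gram of Z + {f} is the running accumulator of Z plus a cached per-feature
contribution. This is exact (tests require agreement with full recomputation
to 1e-8 on the resulting J).

## Selection defaults

`n_star = 100` (the list length used by the stability and similarity
measurements), `r_max = 10` (the length of the effectiveness chain), both
configurable. Ties in ranking and in the greedy rounds break by stage-1
rank, then input order, making runs bit-reproducible. With `skip_stage1`,
stage 2 runs over all features in input-matrix order and ties break by that
order; the stage-1 scores are not computed in that mode. Rejected candidates
remain in the pool and are re-evaluated every round (standard sequential
forward selection); the search never removes an accepted feature.

## Preprocessing

Fixed order: missingness filter -> imputation -> probe merge -> sample
normalization (merging before normalizing is not interchangeable with the
reverse, and the order above is the chain's contract).

* Filter: probes with missing fraction >= 0.20 are dropped ("less than 20%"
  read strictly).
* Local least-squares imputation: each incomplete probe is regressed with
  intercept on its `neighbor_count` (default 10) most-|Pearson|-correlated
  complete probes over the jointly observed samples. Probes constant over
  their observed samples are filled with that constant (their correlation is
  undefined). With fewer complete probes than neighbors the chain falls back
  to row-median filling with a warning.
* Merge: per feature and sample, the maximum over the feature's probes.
* MAD normalization: per sample (column), subtract the median and divide by
  the raw median absolute deviation — no 1.4826 consistency constant, since
  the aim is background equalization and any constant factor cancels under
  the downstream z-scoring. A zero-MAD sample is an error naming the sample.
  A per-feature mode is not provided; normalize externally if needed.

## Evaluation

* **Effectiveness**: for a nested chain S_1 c ... c S_n (default n = 10),
  the stratified 10-fold CV accuracy per S_k; mean and max over k. The
  classifier is the learned multiple-kernel predictor by default; a plain
  linear-SVM mode exists for speed. Fold accuracy is averaged within a
  dataset; when multiple resample groups are evaluated, group means are
  averaged afterwards.
* **Union stability**: |global intersection| / |global union| of the k lists
  selected on k subsamples. **Independent stability**: mean pairwise
  Jaccard. An empty pair union (impossible for fixed-size nonempty lists)
  contributes 0 with a warning.
* **Similarity**: mean intersection *size* — not Jaccard — between one
  method's list and each other method's list; external lists are read from
  one-feature-per-line text files.
* **Resampling**: k = 10 draws of 90% of the samples without replacement.
  Paired samples are drawn, and folded, as pairs: a subject never straddles
  a train/test boundary, which would leak the pair's shared background into
  the test fold.

## Synthetic data

The generator plants the taxonomy the method is meant to resolve:
`k_informative` features with class means at +/- effect/2 and unit
within-class variance, `k_redundant` copies correlated rho with their
parents, and irrelevant Gaussian noise; samples come in tumor/normal pairs,
optionally sharing a per-pair intercept; optional missing-at-random masking
and a log-normal mode for preprocessing tests. Defaults — 30 pairs, 200
features, 10 informative, 10 redundant at rho = 0.9, effect 2 — are the
study conditions used throughout the tests and the acceptance script.

What it does not emulate: count-based mean-variance relationships of
sequencing data, batch effects, heavy-tailed outliers, or correlation
structure among the irrelevant background. Passing the planted-recovery
checks therefore shows the machinery is correct and well-conditioned at
realistic dimensions, not that the method dominates alternatives on real
cohorts.

The probe-level fixture (12 probes, 8 features, 6 samples, 3 masked cells)
is constructed so each masked probe is an exact affine function of complete
probes: the imputation result, and hence the merged matrix shipped alongside
it, is hand-checkable.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full method at the default
conditions (60 samples x 200 features, 20 replicate seeds); the method
itself is O(features) QP solves of size n per stage-1 pass and
O(r_max * n_star) per stage-2 pass, so desk-scale cohorts are comfortable.
The acceptance script's stability measurement uses a top-20 list over 10
resamples of 90% of pairs, its effectiveness chain is the stage-1 top 10,
and the compact-subset accuracy is stratified 10-fold CV — the same routines
as the library defaults at sizes chosen to mirror a single-cohort analysis.

PSD validation of kernel matrices uses a jittered Cholesky (tolerance scaled
to trace/n) rather than a full eigendecomposition. The simplex invariant is
enforced at 1e-8; dual feasibility at 1e-6 * C * n. The two-point instance
(x = -1, +1; linear kernel; C = 10) with alpha = (1/2, 1/2), b = 0,
W = 1/2 serves as the closed-form anchor of the dual solver.

## Known limitations

* Binary classification only; no multi-class extension.
* The greedy stage is deterministic and can lock in a locally optimal subset;
  no backward elimination or randomized restarts.
* The inner QP relies on libsvm's convergence; extremely ill-conditioned
  kernels (far-from-PSD inputs) are rejected rather than repaired.
* Housekeeping-gene cross-platform normalization and miRNA/mRNA consistency
  analysis are out of scope.
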