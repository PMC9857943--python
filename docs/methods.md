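# Methods

## Problem setting

`rifsvm` trains binary classifiers for imbalanced tabular data contaminated
with noise and outliers. The minority class is always coded +1 and the
majority −1. Plain soft-margin SVMs treat every instance's slack equally, so
the separating surface drifts toward the majority class and single mislabeled
points can reshape the boundary. The fuzzy-SVM family addresses both problems
by scaling each instance's slack penalty with a fuzzy value s_i ∈ [0, 1]:
the primal objective becomes

    min_w,b  1/2 ||w||^2 + C Σ_i s_i ξ_i,   y_i (w·φ(x_i) + b) ≥ 1 − ξ_i,

whose dual is the standard SVM dual with per-instance box bounds
0 ≤ α_i ≤ s_i C. Everything in this package reduces to choices of s_i.

## Relative density (KNN-PDE)

Density, not distance-to-centroid, is the reliability signal: noise and
outliers sit in low-density regions regardless of the shape of the class
(small disjuncts, rings, manifolds). For instance x_i, let d_ik be the
Euclidean distance to its k-th nearest neighbor; 1/d_ik is the *relative
density*. Only ratios of these quantities matter, and
(1/d_ik)/(1/d_jk) = d_jk/d_ik, so no density model is ever fit.

Two variants are computed for every training instance:

* **within-class** distance — k-th NN among the instance's own class, with
  the instance itself excluded (an instance is not its own neighbor);
* **between-class** distance — k-th NN among the opposite class.

One k per class: k = ⌈m·√N_class⌉ with multiplier m = 1 by default, clamped
to [1, N_class − 1]. Within-class queries use the own class's k; between-class
queries use the opposite class's k. The √N default balances two failure
modes: tiny k fails to flag noise, huge k flags normal instances. The
multiplier exposes the sensitivity sweep (defaults {1/3, 1/2, 1, 2, 3});
performance is flat for m between roughly 1/2 and 2 and degrades outside.
Neighbor queries use a k-d tree per class (`scipy.spatial.cKDTree`).

## The RIF weighting scheme

Distances are turned into degrees with the exponential decay
g(d; D) = 2/(1 + exp(d/D)) ∈ (0, 1], where D is the maximum of the same
distances over the class being scored: g(0) = 1, g(D) = 2/(1+e) ≈ 0.538.

**Majority instances** get an intuitionistic pair:

* membership μ⁻ = g(d_within; max majority d_within),
* opposite-class affinity ρ = g(d_between; max majority d_between),
* non-membership ν⁻ = (1 − μ⁻) ρ, so μ⁻ + ν⁻ ≤ 1 always,
* score H = 0 if μ⁻ < ν⁻, else (1 − ν⁻)/(2 − μ⁻ − ν⁻),
* final weight s = IR · H, with IR = N⁺/N⁻ the minority-to-majority ratio.

The IR factor rebalances the aggregate slack budget between classes; it is
algebraically identical to a cost-sensitive SVM with C⁻/C⁺ = IR (a unit test
asserts this). With both normalizers taken as class maxima, μ⁻ ≥ 2/(1+e) >
(1 − μ⁻)ρ = ν⁻ always, so the μ < ν branch of H cannot fire; the branch is
retained because the score function is defined piecewise and other normalizer
choices (below) can reach it.

**Minority instances** are weighted by membership alone,
s = μ⁺ = g(d_within; max minority d_within). Computing a non-membership for a
sparse minority class would systematically misjudge its instances as noise —
exactly the failure the scheme is designed to avoid — so ν is not used there.

Normalizer choice: the decay denominator for ρ is the maximum *between-class*
distance over the majority instances being scored (keeping the exponent in
(0, 1] and the construction symmetric with μ⁻). An alternative reading —
normalizing by the minority class's maximum within-class distance — is
available via `rif_majority_nonmembership(..., normalizer="minority-within")`.

## The IFSVM baseline

The centroid-based intuitionistic baseline computes everything in kernel
space: membership μ = 1 − ||φ(x) − c_class||/(R_class + δ) with the class
center c and radius R = max over the class of the center distance, all
evaluated through the Gram-matrix expansion; non-membership ν = (1 − μ) ρ with
ρ the fraction of opposite-class points among all points within kernel
distance β₁ (the counting ball includes the instance itself). The weight is
the score function applied to both classes: s = μ if ν = 0, 0 if μ < ν, else
(1 − ν)/(2 − μ − ν). Defaults δ = 10⁻⁴ and β₁ = min(R⁺, R⁻)/5. Because these
weights live in kernel space, they are recomputed for every kernel bandwidth
during model selection.

## Dual solver

The weighted dual is solved by sequential minimal optimization with
second-order working-set selection (the maximal violating pair for the first
index, the best one-step decrease for the second), compiled with numba. The
stopping rule is the violating-pair gap m − M < tol with tol = 10⁻⁶; the
iteration cap inside the evaluation protocol is 3·10⁵ pair updates (a cap a
fit at these problem sizes rarely approaches outside the most extreme C
values). The solver is deterministic given input order. The bias is the mean
of y_i − Σ_j α_j y_j K_ij over free support vectors (strictly inside the
box), falling back to the midpoint of the feasible interval implied by the
bound constraints. Support vectors are α_i > 10⁻⁸ · C · max(s). The Gram
diagonal receives a 10⁻¹⁰ jitter only if an (optional) PSD check fails
marginally; RBF and linear self-Grams are PSD by construction, so the check
is off by default.

Numerical contract, verified by tests rather than assumed: KKT conditions at
ε = 10⁻⁴ on random problems; dual objective equal to an independent dense-QP
solve (SLSQP plus exact active-set polish) to 10⁻⁶ on small problems;
decision values equal to a reference SVM implementation to 10⁻⁴ when all
s_i = 1; zeroing a weight is equivalent to deleting the instance.

## Synthetic data generators

Two presets emulate geometries where centroid-based weighting fails:

* **data1** — three isotropic Gaussians with per-axis spread 0.1: 800
  majority points at (0.4, 0.4), minority points 50 at (0.15, 0.15) and 150
  at (0.7, 0.7) (a small disjunct plus a main minority cluster), IR 1:4. The
  classes overlap, so test G-means sit in the mid-90s.
* **data2** — concentric rings centered at the origin, band width 0.2,
  minority radii [0.3, 0.5], majority [0.6, 0.8]. The published source states
  only the 1:5 ratio, not absolute counts; the preset uses 100/500 to match
  data1's scale. Angle is uniform on [0, 2π), radius uniform on the band —
  the simplest law consistent with a fixed band width. The radial gap of 0.1
  makes the classes separable: a correctly tuned RBF model reaches G-mean 100.

The Gaussian spread parameter is read as an isotropic per-axis standard
deviation (diagonal covariance-style parameter, no correlation). Generators
are pure functions of (spec, seed).

What these generators deliberately do *not* emulate: feature noise or label
noise beyond the class overlap itself, non-numeric attributes, missing
values, and high-dimensional or heavy-tailed feature distributions. Passing
the synthetic checks therefore demonstrates correct handling of imbalance
plus geometric structure, not performance on arbitrary real data.

## Evaluation protocol

Metrics are on the percent scale with the minority class positive:
sensitivity, specificity, G-mean = √(Se·Sp), F-measure, and AUC. AUC uses the
tie-corrected Mann–Whitney rank statistic on continuous decision values
(pre-sign); an estimator based on hard labels would collapse to (Se+Sp)/2.

The protocol is 10 repeats of a stratified 80/20 holdout. Within each repeat,
C ∈ {10⁻⁵…10⁵} and h ∈ {2⁻⁵…2⁵} (RBF K(x,x′) = exp(−h‖x−x′‖²)) are chosen by
stratified 5-fold CV on the training part, maximizing mean fold G-mean; ties
break toward smaller C, then smaller h (regularization first). Repeat r uses
seed base + r for both the split and the folds. Aggregates are arithmetic
means of per-repeat metrics — the per-repeat-then-average convention, not
metrics of pooled counts (the two differ, and reference result tables are
consistent only with the former). Min-max normalization is applied to the
full dataset before splitting by default, mirroring common benchmark
practice; a leakage-free per-split mode (fit on train, apply to test) is
available via `Protocol(normalize="per-split")`.

Grid search reuses work aggressively: squared-distance matrices are computed
once per fold, RBF Grams derived per bandwidth, relative-density weights
computed once per fold (they do not depend on the kernel), and centroid
weights once per (fold, bandwidth).

## Statistical comparison

Scores of k algorithms over n datasets are ranked per dataset (best = 1, ties
averaged — the convention that exactly reproduces the reference table's
printed average ranks; no tie-correction factor is applied to the statistic).
The Friedman chi-square Γ = 12n/(k(k+1))·(Σ r̄_j² − k(k+1)²/4) and its less
conservative F-form τ_F = (n−1)Γ/(n(k−1) − Γ) with ((k−1), (k−1)(n−1))
degrees of freedom decide whether performances differ; the Nemenyi critical
difference CD = q_α √(k(k+1)/(6n)) (two-tailed studentized-range constants,
tabulated for k = 2..10 at α ∈ {0.05, 0.10}) identifies which pairs do. The
packaged fixture is a transcription of a published 20-dataset × 8-algorithm
comparison, one CSV per metric.

## Known limitations

* Binary classification only; no multiclass decomposition.
* The SMO solver holds the full Gram matrix; fine up to a few thousand
  instances, not designed for large-scale problems.
* Relative-density distances are computed in input space. A flagged
  kernel-space variant is deliberately not provided: the weighting scheme is
  defined on input-space geometry, and its neighbor distances would otherwise
  change under every candidate bandwidth during tuning.
* The score-table comparison assumes complete tables (no missing cells).
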