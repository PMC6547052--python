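# Methods

## Model

The classifier operates on a subjects × features matrix assembled from
one or more 3-D images per subject (in-mask voxels, one column each) and
a table of clinical/demographic variables. Each feature group — in the
fully fragmented family, each single column — defines a linear base
kernel `K_r = X_g X_gᵀ`. Seven kernel families are supported, from a
single kernel over the concatenation of everything (`I_plus_C`) to one
singleton kernel per voxel and per clinical variable (`V_and_C`); the
family is the unit at which weights are learned and features selected.

Base kernels are trace-normalized so each contributes unit mass:
`K̂_g = K_g / Tr(K_g)`. For a linear kernel this is a column rescaling,
`s_g = (Σ_{r∈g} ‖x_r‖²)^{-1/2}`, which is how the whole method stays in
feature space: the average kernel is `K_A = X̃X̃ᵀ / R` on the rescaled
matrix, and no per-kernel Gram is ever materialized. Memory beyond the
data matrix is O(ℓ + m); this is the property that makes a family of
~10⁵–10⁶ kernels tractable.

The kernel-weighting step solves, for λ ∈ [0, 1],

    min_{γ ∈ Γ} (1 − λ) γᵀ Ŷ K_A Ŷ γ + λ‖γ‖²,
    Γ = {γ ≥ 0, Σ_{y=+1} γ_i = 1, Σ_{y=−1} γ_i = 1},

a convex QP whose solution is a pair of distributions over the two
classes. λ = 1 gives the closed-form per-class uniform solution; λ = 0 is
the distance between the class convex hulls. The raw weight of kernel g
is the quadratic form `d_g = γᵀ Ŷ K̂_g Ŷ γ = ‖X̃_gᵀ(Ŷγ)‖²`; weights are
L1-normalized to η (Σ η = 1). The sparse model keeps exactly the kernels
with `η_r > ρ` (strict inequality, so equality with the threshold
removes), combines them with their *unrenormalized* weights into
`K* = Σ η_r K̂_r`, and trains a soft-margin SVM (cost C) on the
precomputed K*. ρ = 0 reproduces plain multiple kernel learning; the
package asserts this equivalence to 1e−8 in its test suite.

### Assumptions

- Binary labels (±1); some features separate the groups despite
  within-group heterogeneity; different sources may carry complementary
  information.
- Linear base kernels only. Single-feature non-linear kernels would add
  hyperparameters without changing the single-feature geometry.
- Test-time normalization reuses the training scales `s_g`; predictions
  are therefore invariant to positive per-column rescaling of the raw
  inputs and no information flows from test rows into the fit.

## Tunable parameters

| parameter | meaning | default / grid | notes |
| --- | --- | --- | --- |
| λ | QP regularization: margin term vs ‖γ‖² | grid {0.0, 0.1, …, 1.0} | λ=1 uniform γ; λ=0 hull distance |
| ρ | weight threshold | grid {i/R : i = 0..20} | R = number of base kernels; for singleton families this equals the per-feature rule |
| C | SVM cost | grid {0.1, 1, 5, 25} | K* has unit-order trace, so informative fits often need the upper end |
| drop fraction | RFE / t-test elimination per stage | 0.05 | drop count max(1, round(0.05·retained)) |
| FDR α | clinical pre-filter level | 0.01 | excludes label-correlated clinical features (anti-circularity) |

Validation is a joint grid over (λ, ρ, C), scored by mean inner-fold
balanced accuracy, ties resolved toward the first point in declared grid
order. Grid evaluation is factorized: normalization and K_A once per
split, γ/η once per λ, K* once per (λ, ρ), an SVM per C.

## Evaluation protocol

Five repetitions of a nested 10-fold cross-validation. Outer folds are
balanced on the label and matched on age: within each class, subjects are
sorted by age (seeded tie-break) and dealt round-robin into folds from a
random starting fold, which keeps per-fold class counts within one and
per-fold age means within a fraction of the within-class sd. Inner folds
(on the outer-train set only) choose the hyperparameters; the model is
refit on the outer-train set and scored on the held-out fold by balanced
accuracy, 100·(sensitivity+specificity)/2. Reported spread is the sd over
all 50 outer-fold scores (repeats × folds); the choice of pooling over
both is a package decision, as is using the 50 paired per-fold scores as
the unit of the Wilcoxon signed-rank comparisons (per-subject pairing is
available via the stored per-subject predictions).

The clinical pre-filter (two-sample Welch t per clinical column, BH-FDR,
exclude adjusted p < 0.01) is by default applied once to the full dataset
before CV — it only *removes* label-correlated features, so it cannot
inflate accuracy — and a strict in-fold mode recomputes it inside every
outer-train set.

The Wilcoxon signed-rank test drops zero differences, averages tied
ranks, enumerates all 2ⁿ sign patterns exactly for n ≤ 15, and otherwise
uses the normal approximation with tie and continuity corrections. The
Bonferroni threshold for comparing one method against k others is α/k.

## Numerical choices

- **QP solver.** Deterministic FISTA (accelerated projected gradient with
  gradient restart) with exact Euclidean projection onto each class
  simplex; fixed step 1/L with L from the largest eigenvalue of the
  quadratic term. Stopping: fixed-point residual of the projected
  gradient step below 1e−10 in max norm (≈1e−8 on the objective for
  unit-trace kernels), cap 10⁵ iterations. No randomness anywhere in the
  solver; identical inputs give identical γ.
- **Zero-norm columns** carry no kernel mass. Zero-norm singleton groups
  are dropped (with a warning and a record) and the family size R used in
  K_A shrinks accordingly; a multi-column group that is entirely
  zero-norm raises an error, since a dead source is more likely a data
  fault than a degenerate feature.
- **Degenerate thresholds.** A grid point whose ρ kills every kernel is
  scored −∞ during validation (never chosen while any feasible point
  exists); a final fit with an empty selection raises with advice to
  lower ρ.
- **Sign convention.** A decision value of exactly 0 predicts +1.
- **Raster order.** In-mask voxels are ordered by ascending (z, y, x)
  voxel index; weight volumes are written back in the same order, so
  load → write → load is the identity on in-mask values.
- **Missing clinical cells** are an error by default; optional mean
  imputation exists and must be fed training rows only when used inside
  CV.
- **Labels** are accepted as {0, 1} or {−1, +1} and stored as ±1.

## Synthetic data

The generator emulates the structure of two study designs: a single
structural image per subject, or four task-contrast images per subject,
plus 20–50 clinical variables, n of order 10²–10³ features and tens of
subjects per class. Background voxels are iid standard Gaussian; signal
voxels, inside spherical blobs (optionally grown in nearest-voxel order
to an exact planted count), are shifted by ±d/2 per class; a few clinical
features likewise. Label noise flips exactly round(rate·ℓ) labels after
the signal is planted, emulating unreliable diagnoses; age is drawn
independently of the label unless an age-confound offset is requested. An
atlas assigns each blob its own region plus octant background regions so
region ranking is testable. Everything is reproducible from the seed.

What the generator does *not* emulate: spatial autocorrelation and
smoothing of real images, haemodynamic response structure, site and
scanner effects, non-Gaussian clinical distributions, and correlated
noise between features. Passing tests on this generator therefore
demonstrate correctness of the algorithms and protocol — recovery of
planted sparse signal, absence of leakage, calibration of the
statistical machinery — not clinical-level accuracy on real cohorts,
where the published headline accuracies require access-restricted data.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run at desk scale: oracle
equivalences on ℓ=15, m=40 instances; planted-signal recovery on ten
simulated studies of 100 subjects × (12³ voxels + 20 clinical) with 20
planted voxels at d = 1.5 and 3 informative clinical features; and a full
5-repeat nested 10-fold cross-validation on a 60-subject study with
~1750 features at effect size 1.0 and 10% label noise, using reduced
λ/ρ grids (λ ∈ {0.2, 1.0}, ρ ∈ {0, 2/R, 5/R}) with the full C grid.
These sizes are the package's demonstration setting; the implementation
itself streams over the feature matrix and handles the full ~7×10⁵-kernel
families (the family-size checks construct them explicitly).

## Known limitations

- Binary classification only; no probability calibration.
- The kernel-count rule for the one-kernel-per-image family follows "one
  kernel per image plus one per clinical feature"; multi-image studies
  summarized elsewhere with a single image kernel will show a different R.
- With very noisy labels, the feature-selection step may not improve on
  plain kernel weighting; the threshold grid includes ρ = 0 so validation
  can fall back to the dense model.
- The FDR pre-filter's default full-dataset mode is a documented
  protocol choice; use the in-fold mode for a fully nested variant.
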