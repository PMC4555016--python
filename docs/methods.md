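# Methods

This note documents the models and procedures `brainclass` implements,
the numerical choices behind them, what the synthetic phantoms do and do
not emulate, and the design decisions taken where the problem left the
design open.

## Pipeline model

The classification target is a binary diagnostic label attached to
spatially normalized 3D tissue maps (whole-brain WB, gray matter GM,
white matter WM) sharing one voxel grid. The pipeline treats images as
flat vectors; no anatomical prior, atlas, or brain mask is assumed
(an optional voxel mask is supported for efficiency).

**Smoothing.** Isotropic Gaussian smoothing with a given FWHM (mm) is
applied per image before flattening; sigma per axis is
FWHM / (voxel_size · 2√(2 ln 2)) voxels. Boundary handling is
nearest-edge replication: interior mass is preserved to well under 0.1%
and constant images remain exactly constant. `fwhm=None` is the
identity. Smoothing is linear and per-image, so it can never move
information between subjects.

**PCA via the Gram matrix.** For an S × N training matrix with N ≫ S,
the covariance eigenvectors are recovered from the S × S Gram matrix of
the centered data: if G = XcXcᵀ/(S−1) has eigenpairs (λⱼ, uⱼ), the
loading is vⱼ = Xcᵀuⱼ/√((S−1)λⱼ). Covariance normalization is
1/(S−1). Components with eigenvalue ≤ 1e−10 × (largest eigenvalue) are
treated as numerically zero and dropped, which enforces the PC ≤ S − 1
bound. Loading signs are fixed by making each column's
largest-magnitude entry positive, so results do not depend on the
linear-algebra backend's sign conventions. PCA (and everything
downstream of it) is always fit on training samples only; validation
and test samples are projected with the training model.

**FDR ranking.** Per component, FDR = (μ₁−μ₂)²/(σ₁²+σ₂²) from the class
means and variances of the component's coefficients. Class variances
use the unbiased (ddof = 1) estimator — the choice only rescales scores
by class-size constants and cannot change an ordering within a fixed
pair of class sizes, but it is documented here because both conventions
exist. Ties break toward the lower original component index. A
component whose two classes are point masses at different values gets
an infinite score (perfectly separating); identical point masses score
zero.

**Classifier.** A soft-margin linear SVM, C = 1.0 by default. C is a
config parameter but deliberately *not* part of the cross-validated
grid, which searches exactly three things: tissue map, smoothing FWHM,
and number of FDR-ranked components. No class weighting is applied (the
evaluation metric, balanced accuracy, is itself robust to imbalance);
this too is configurable. The solver is scikit-learn's `SVC` with a
tight stopping tolerance (1e−8) so that label-flip symmetry and
rerun determinism hold to small tolerances; the module exposes the dual
weights wₙ ≥ 0, the label signs tₙ, the bias b, and the primal vector
w = Σₙ wₙtₙxₙ, and the dual-form decision function is checked against
the primal form on every model in the tests. A decision value of
exactly 0 is mapped to the positive class. The positive class defaults
to the larger label value (patients coded 1, controls 0), so
"sensitivity" always refers to patients.

**Covariates.** Scalar covariates (e.g. MMSE) are standardized with
training-set mean/sd and appended to the selected components; the same
training statistics are applied to validation/test rows. Zero-variance
or missing covariates are an error.

**Nested cross-validation.** The outer loop is a seeded stratified
k-fold partition (stratification prevents single-class folds at k = 20
with imbalanced groups; fold sizes differ by at most 1 per class). For
each outer fold, the inner set (the remaining (k−1)/k of subjects) is
split stratified 50/50 (seeded); for every (tissue, FWHM) pair a single
PCA + FDR fit on the training half serves the whole component sweep
n = 1..PC — mathematically identical to refitting per n — and the
configuration minimizing validation E is selected. Ties break by fewer
components, then smaller FWHM (none < 2 mm), then tissue order
GM < WB < WM; the ordering is arbitrary but fixed, and on real data
near-ties between adjacent smoothing levels are common, so an explicit
rule is needed for reproducibility.

Two refit policies for the outer prediction are implemented because the
procedure is genuinely ambiguous at this point:

* `refit="full"` (default): refit PCA, FDR, covariate statistics and
  the classifier on the *entire* inner set under the chosen
  configuration, then predict the held-out fold. This uses all
  available training data and is the default because discarding half
  the inner set at prediction time wastes sample size for no
  statistical benefit.
* `refit="half"`: reuse the half-trained model from the inner search
  directly.

Both are leakage-free: nothing computed from an outer test subject
enters that fold's model (this is asserted in the tests by corrupting a
fold's held-out images and checking the fitted model is bit-identical).
The headline statistic is the Overall Balanced Accuracy: the arithmetic
mean (± sd) of the per-fold balanced accuracies; pooled-confusion
evaluation over all outer predictions is also available and is what the
null-calibration check uses.

**Biomarker maps.** A linear classifier's weight vector is a backward
model; to interpret it spatially it is converted to a forward
activation pattern a = Σₓ w, where Σₓ is the (unbiased) sample
covariance of the classifier's training features. In the general
formulation the pattern is Σₓ W Σ_ŝ⁻¹; for a single-output model Σ_ŝ is
a scalar and is absorbed by the final [0, 1] rescaling, so it is
dropped. The weighted-sample sum includes the label factor
(w = Σₙ wₙtₙxₙ): without tₙ the two classes' support vectors add
instead of oppose, making the map reflect class imbalance rather than
discrimination; a `signed_by_label=False` flag provides the unsigned
variant. The pattern's component entries are back-projected through the
selected FDR-ordered loadings and scattered to the 3D grid (covariate
entries have no voxel location and are not back-projected). Per-fold
maps are computed under each fold's own optimal configuration, averaged
voxelwise on absolute values — folds may select different
configurations, so global map sign is not comparable across folds and
per-fold maps are not rescaled before averaging — then min-max
normalized to [0, 1]. Thresholding zeroes voxels below the cut
(typical display cuts 0.50/0.45/0.35) and exports float32 NIfTI with a
reference affine for overlay.

## Synthetic phantoms

The phantom module emulates the statistical skeleton of a two-group
structural-MRI study: a shared anatomical background (Gaussian random
field smoothed at 8 mm FWHM, rescaled to [0.2, 1]; one realization per
dataset so between-subject variance comes only from noise and group),
three nested tissue channels carved from that background by smooth
radial masks (WB ⊃ GM ⊃ WM support, all equal to 1 at the grid centre),
localized atrophy as a multiplicative intensity reduction (1 − effect)
inside spherical ROIs with a one-voxel linear ramp at the boundary (a
knife edge would be unrealistic relative to smoothed real data), and
i.i.d. additive Gaussian voxel noise per subject and channel. The
atrophy is injected into the GM channel only by default, so the tissue
hyperparameter has a correct answer the search must find. Defaults — a
20³ grid at 2 mm, 30 subjects per group, one 8 mm-radius ROI, effect
0.5, noise sd 0.05 — are the standard validation conditions used by the
tests (the null-calibration check sets effect 0 with 20 per group, and
the signal-recovery check uses effect 0.6).

What the phantoms do *not* emulate: scanner artifacts, multi-site
intensity differences, registration error, anatomically shaped (rather
than spherical) atrophy, correlated noise, or realistic cortical
geometry. Passing phantom tests therefore demonstrates that the
machinery is correct and leakage-free and that known signal of a given
strength is recovered and localized — not that any particular accuracy
will be attained on clinical cohorts.

## Numerical and scale choices

* Grids of 20³ voxels and 20–60 subjects are used for validation runs;
  they preserve the defining regime N ≫ S (8000 ≫ 60) while keeping a
  full 3 × 7 × PC hyperparameter search fast.
* Determinism: every stochastic step (phantom generation, fold
  assignment, inner splits) derives from explicit integer seeds; a full
  pipeline rerun is bitwise identical (tested).
* Degenerate inputs: rank-0 datasets, single-class splits, empty masks,
  zero-variance covariates, constant maps, and out-of-grid ROIs all
  raise informative errors rather than propagating NaNs.
* The explained-variance curve (optionally in FDR order) is exposed
  because the variance retained by the first k *discriminative*
  components is a useful diagnostic of how concentrated the class
  signal is; it is monotone and ends at 1 by construction.

## Known limitations

* Only binary tasks; multicategory classification is out of scope.
* The inner loop uses a single seeded split-half per outer fold;
  repeated inner splits would reduce selection variance at proportional
  cost and could be added without changing the contracts.
* `predict` applies a single saved fold model (default: the fold with
  the lowest inner validation error); it does not ensemble folds and
  does not yet accept covariate tables.
* NIfTI affines are carried, not interpreted: inputs must already be on
  a common grid (spatial normalization is upstream of this package).
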