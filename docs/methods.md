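# Methods

This note documents the models and procedures implemented in `kneetwin`,
the parameters that matter, the numerical choices behind them, and what the
synthetic phantoms can and cannot establish.

## Synthetic knee phantom

The `phantom` module stands in for segmented clinical MRI. Geometry is
deliberately parametric-primitive so that every downstream measurement has
a closed-form truth:

* **Bones** — ellipsoids (femur, tibia, patella) with millimetre-scale
  placements leaving anatomically motivated gaps between tissues.
* **Cartilage** — Euclidean-offset shells over a polar cap of the parent
  bone: a voxel belongs to cartilage when its distance to the bone surface
  is in (0, t(θ)], with t(θ) = t₀·(1 + v·sin θ) (defaults t₀ = 2.5 mm,
  v = 0.1). Shell thickness is therefore analytic by construction, even
  under deformation.
* **Menisci** — torus sectors in the joint space.

**Population shape variation** is a low-rank field. Smooth sinusoidal
vector fields (wavelength 90 mm) are orthonormalized at each tissue's
reference landmarks, so a subject's landmarks are `mean + B @ scores` with
`B` orthonormal over the flattened 3L-vector. Mode scores then use the same
norm convention as statistical-shape-model scores, which makes per-mode
variance recovery a well-posed question: PCA on the true landmark matrix
returns exactly the planted score SDs. Defaults are 3 modes with SDs
(20, 14, 8), i.e. RMS surface displacements of roughly 0.5/0.36/0.2 mm at
the default 500 landmarks — population-scale variation that stays small
against inter-tissue gaps.

Two numerical safeguards matter here. First, the orthonormalizing mix of
the raw fields is accepted only if its coefficients stay bounded
(max ≤ 5/√(3L), redrawing the wave directions deterministically otherwise):
a near-degenerate raw set would make the continuous field between landmarks
much larger than its at-landmark norm. Second, label placement resolves
thin contact overlaps at extreme score draws by carving in canonical tissue
order — tissues cannot interpenetrate — and raises an error only when a
tissue would lose more than 10% of its volume, which indicates genuinely
broken geometry. Verified over 144 label maps across 12 seeds including
±3.5σ scores without a failure.

**Signals.** Multi-echo stacks follow `S(TE) = α·exp(−TE/T2) + C` per voxel
with per-tissue parameters (cartilage α = 100, C = 2; deep/superficial
cartilage T2 = 35/55 ms split at half the shell thickness; bone 15 ms;
meniscus 18 ms). Noise is additive Gaussian, default SD 2 (SNR ≈ 50 in
cartilage); no published acquisition noise level exists for this design, so
the default was chosen once to make T2-recovery tests meaningful. A Rician
option (`rician_noise=True`) is available; the Gaussian default keeps the
fitting oracle simple.

**Cohort tables.** Covariates (age, BMI, pain, sex, race, injury history)
are drawn from population-typical distributions; the binary outcome comes
from `logit(p) = β₀ + Σβⱼ·featureⱼ + Σγ_c·z(cov_c)` with planted β stored
in the ground truth. Confounding is planted by shifting configured
covariates in the case group by a stated number of SDs, so the pre-matching
SMD is known in closed form. Longitudinal Kellgren–Lawrence grades and
surgery flags are emitted so that outcome derivation reproduces the drawn
labels exactly. Missingness is missing-completely-at-random at a configured
rate (rates ≥ 100% of a column are rejected).

## T2 relaxometry

`fit_t2_voxel` is the scalar contract: Levenberg–Marquardt least squares
with the analytic Jacobian, initialized at α₀ = S(TE₁) − S(TE_last),
C₀ = S(TE_last), and T2₀ from the two-point log slope. Fits with T2 outside
(0, 2000] ms retry with a bounded trust-region solver and are flagged
non-converged — never clamped or imputed; constant signals are reported
unidentifiable. `t2_map` runs the same model through a vectorized batch LM
(per-voxel damping, analytic Jacobian) over all in-mask voxels, which is
what makes whole-knee maps affordable; the two routes agree to solver
tolerance and are cross-checked in the tests, with a profile-likelihood
grid search as an independent oracle for the noisy-recovery RMSE. At SNR 50
the estimator's median is within a fraction of a percent of truth; the
per-voxel spread is the intrinsic variance of the three-parameter fit at
six echoes, as the grid-search oracle confirms.

`rigid_resample` applies one rigid transform (estimated from the first
echo, by contract an input here) to every echo with cubic interpolation.
Voxels mapping outside the source are marked invalid through a propagated
validity mask and zero-filled — never NaN, which would contaminate the
global spline prefilter of any subsequent resampling.

## Cartilage thickness

Thickness = 2 × EDT at the morphological skeleton, in mm with anisotropic
spacing. Two discretization choices were settled against analytic oracles:

* The distance is measured to the 0.5 level of the trilinearly
  interpolated mask, sampled 4× finer. A coarse EDT reads distances to
  background voxel *centres* (half a voxel too far per side on flat
  axis-aligned boundaries), while a nearest-neighbour refinement measures
  to the voxel-cube staircase (up to half a cube diagonal too near on
  oblique ones); the interpolated level set is orientation-unbiased.
* Discrete skeleton voxels sit up to about half a voxel off the true
  medial ridge, which biases 2×EDT low. Since the EDT cannot exceed the
  true half-thickness, the estimator reads the EDT's local maximum within
  ¾ voxel of each skeleton voxel, recovering the ridge value without
  overshooting on constant-thickness bodies.

With both, slab (5 mm), spherical shell (5 mm), anisotropic slab (6 mm) and
a 30°-oblique slab are all recovered within half a voxel.

**Projection.** For each bone-surface vertex a ray marches along the
outward normal (step = ¼ of the smallest voxel dimension, normals oriented
away from the mesh centroid); the first/last in-cartilage samples bound the
chord. Thickness mode records the chord length; scalar mode averages a
supplied volume (e.g. the T2 map) over the chord — deep = proximal half,
superficial = distal half, split at the chord midpoint with the odd sample
assigned to deep, total = full chord, so the total equals the
count-weighted mean of the two layers exactly. Rays that never enter
cartilage leave the vertex invalid. Non-converged T2 voxels are NaN before
projection and so excluded from layer averages.

## Statistical shape model

Marching cubes runs on a lightly Gaussian-smoothed (σ = 1 voxel) copy of
the binary mask: raw binary contouring produces a staircase that inflates
the area of a digitized sphere by ~9%, while the smoothed 0.5 level is
within 3%. Zero-area sliver triangles are dropped.

ICP is rigid-only (no scaling), alternating nearest-neighbour
correspondence with Kabsch estimation; degenerate (coplanar) clouds are
rejected. The reference knee is selected by registering all candidate
clouds into the current candidate's frame and choosing the cloud with the
smallest summed symmetric nearest-neighbour RMS to all others, iterated to
stability with ties broken to the lowest index. The pipeline restricts the
candidate pool (default 20 subjects) because the selection is quadratic;
the choice of reference is not critical once the pool is representative.

Landmarks (default 500 per tissue, farthest-point sampled from the
reference mesh) transfer to each registered subject by nearest-neighbour
search in a weighted feature space of position, mean curvature and Gaussian
curvature (weights 1, 0.5, 0.5). Curvatures come from quadric patches over
k-nearest-neighbour vertex neighbourhoods (k = 12) fitted in the vertex
normal frame — a vectorized equivalent of 2-ring quadric fitting at the
uniform sampling marching cubes produces. Curvature channels are
standardized by the reference spread and scaled by the mesh's mean edge
length, so a unit weight trades one SD of curvature against one edge length
of position; with zero curvature weights the matching reduces exactly to
nearest-vertex search.

Per tissue–biomarker pair, PCA is fitted on flattened 3L landmark
coordinates (shape) or the L-vector of projected scalars restricted to the
cartilage-covered landmarks of the reference subject (thickness, T2;
uncovered landmarks carry 0 mm thickness, subject-mean T2). Mode SDs are
the square roots of the Bessel-corrected explained variances; mode
synthesis returns `mean + k·SD·component` with |k| capped at 3 by default.
Constant data yields a zero-variance model flagged degenerate rather than
an error.

## Cohort construction and matching

Outcome rules: an OA-incidence case has KLG < 2 at baseline and KLG ≥ 2 at
any follow-up, a control KLG < 2 at every visit, anything else is excluded
(including missing baseline, which is logged); a knee-replacement case has
partial or total replacement after baseline. Filtering keeps right-knee
rows, drops subjects missing any PC-mode value, and drops covariates more
than 5% missing. Remaining gaps are imputed by a round-robin random-forest
imputer (classifier for categorical, regressor for continuous, initial
mode/median fill, 3 sweeps) — a per-column-estimator design sklearn's
single-estimator iterative imputer cannot express; observed entries are
never altered and the result is seed-deterministic. A two-sample
Kolmogorov–Smirnov sensitivity check compares pre- and post-imputation
distributions.

Matching embeds the union of case and control rows (the union is required
for distances to be comparable) after z-scoring continuous and
integer-encoding categorical covariates, into 3-D t-SNE with perplexity
√N rounded, floored at 5, and capped at N−1. t-SNE is stochastic: the seed
is mandatory configuration and downstream results are per-seed. Each case
takes the control with minimum embedded Euclidean distance, with
replacement by default; ties break to the lowest control index, and the
nearest-neighbour step is computed from the full distance matrix so it is
exactly checkable against brute force. Balance reports Cohen's d with
pooled SD = √(mean of the two Bessel-corrected group variances),
point-biserial r, Wilcoxon signed-rank on matched pairs, Shapiro–Wilk and
Anderson–Darling screens, and Cramer's V with chi-squared for categorical
covariates — uncorrected, as diagnostics rather than hypothesis tests.

## Cross-sectional testing

Per feature, a two-sided Wilcoxon rank-sum test: exact null distribution
when both groups have ≤ 25 observations without ties, tie-corrected normal
approximation otherwise; all-tied input returns p = 1 with a flag.
Family-wise adjustment is the standard Benjamini–Hochberg step-up
estimator, `P′(i) = min_{j≥i} min(1, (m/j)·P(j))`, verified element-wise
against a brute-force double loop and against statsmodels; Hochberg's
sharpened family-wise procedure is available behind a flag for comparison.
Significance tiers follow the `*/**/***` convention at 0.05/0.01/0.001 on
adjusted p. Percentile-bootstrap 95% and 99% intervals (default 1000
resamples, seed-deterministic) are reported for the case–control median
difference — the bootstrapped statistic is a package choice.

## Stability selection and the final model

For each of `n_boot` bootstrap resamples (rows with replacement; one-class
resamples are redrawn and logged), an elastic-net-penalized binomial GLM
(saga, mixing 0.5) is fitted to the standardized design. The penalty is
chosen once by 5-fold cross-validated log-loss on the full sample and held
fixed across bootstraps — selection frequencies are only comparable under a
fixed penalty. A feature is selected when |coefficient| > 1e-5; the mean
coefficient averages over all fits including zeros, so importance =
frequency × |mean coefficient| shrinks for rarely selected features.
Retention keeps scores ≥ the linear-interpolation 75th percentile
(inclusive); all-equal scores retain everything with a warning. The final
model is an unpenalized statsmodels binomial GLM on the retained features
reporting Wald p-values, 95%/99% intervals, OR = exp(β), McFadden
pseudo-R², and Pearson chi-squared; perfect separation and rank-deficient
designs raise errors naming the offending columns.

## What the phantoms establish — and what they do not

Passing tests show the *algorithms* are correct: exact model inversion,
orientation-unbiased thickness, recoverable planted shape modes, valid
nearest-neighbour matching, FDR control, and recovery of planted outcome
predictors. The phantoms do not emulate MRI artifacts (bias fields, partial
volume, motion), realistic anatomy, segmentation error, or non-MCAR
missingness, so the tests say nothing about robustness to those; the
out-of-scope segmentation networks are replaced by the generator entirely.

## Problem sizes

The acceptance script runs the full image pipeline at 100 subjects on 64³
grids with 1.5 mm voxels (~70 s), shape recovery at 500 subjects on the
generator's ground-truth landmark matrices, 100 matching replicates,
200 global-null replicates with m = 110 and 300 per group, 50
stability-selection replicates at n = 600 with 200 bootstraps, and 200
calibration replicates of the final GLM — sizes chosen to make the
statistical checks sharp while keeping a full run within minutes on one
CPU.
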