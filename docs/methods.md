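# Methods

This note records the modeling choices behind `deltarad`: what each stage
assumes, the conventions that matter for reproducing numbers, and the
known limitations.

## Grids and I/O

Volumes and masks live on axis-aligned grids: the physical position of
voxel `(i, j, k)` is `origin + index * spacing` (mm), with identity
direction cosines. All time points of a patient are assumed
co-registered into one frame of reference; registration itself is out of
scope. The default grids mirror a whole-body PET/CT protocol: CT voxels
1.37 × 1.37 × 3.27 mm, PET voxels 5.47 × 5.47 × 3.27 mm, sharing slice
spacing and physical center.

SUV is body-weight normalized — `SUV = c · w / D` with `c` the
decay-corrected activity concentration in kBq/mL, `w` the body weight in
kg and `D` the injected dose in MBq — assuming tissue density 1 g/mL. No
decay-timing model is applied; concentrations are taken as already decay
corrected. Lean-body-mass normalization is not implemented; body-weight
SUV is the common default when the normalization is unstated.

The GTV is delineated on the CT grid; the PET-grid GTV is always derived
from it by nearest-neighbor resampling in physical coordinates. Geometry
features are computed per modality on the native grid, which is why e.g.
the SUV-side surface-voxel count is a distinct (coarser) feature from its
CT counterpart. Volume resampling is trilinear, exact on affine fields;
out-of-extent voxels are filled with −1000 HU (CT) or 0 (SUV).

## Geometry features

Definitions follow classic image-toolkit shape-attribute conventions:
volume is the foreground voxel count and physical size its mm³
equivalent; major/minor axis lengths are `4·sqrt(λ1)` and `4·sqrt(λ3)` of
the voxel-center covariance eigenvalues (best-fit-ellipsoid convention,
so a solid ellipsoid of semi-axis `a` yields `4a/√5 ≈ 1.79a`);
eccentricity `sqrt(1 − λ3/λ1)`; elongation `sqrt(λ1/λ2) ≥ 1`; orientation
is the angle between the first eigenvector and +x folded to [0, π/2] (a
full 3D orientation is not a scalar). The oriented bounding box is the
principal-axes-aligned box of voxel centers padded by the projected voxel
footprint. Feret diameter is the maximum pairwise distance of foreground
voxel centers (via the convex hull). "Number of pixels on border" counts
object-surface voxels (face-adjacent to background), not voxels on the
scan border — tumors never touch the scan border, so the latter would be
degenerate. "Perimeter on border" is the exposed face area on the mask's
tight bounding box.

Surface area ("perimeter", the `v` of roundness `R = A/v`) is measured on
a marching-cubes iso-surface at level 0.5 after Gaussian pre-smoothing of
the binary mask with **σ = 0.6 voxels per axis**. A mesh on the raw
binary mask inherits the voxel staircase and overestimates a ball's
area by ~7–13%, biasing roundness down to ~0.92 for a perfect sphere;
σ = 0.6 restores ball areas (radius ≥ 8 voxels, isotropic or anisotropic
grids) to within ~2% and ellipsoid areas to within ~3% of quadrature
values, while larger σ begins to erode high-curvature shapes. Roundness
is scale invariant and rotation invariant to within ~2% under digital
rotation.

## Intensity and texture features

Intensity statistics use population (n) denominators and non-excess
kurtosis (a Gaussian scores 3); both conventions are recorded in the
result metadata. A constant region returns skewness/kurtosis 0 with a
flag. Median of an even count is the midpoint of the central order
statistics.

Texture quantization maps ROI intensities linearly into 64 equal-width
bins between the ROI's own minimum and maximum (so features are invariant
to positive affine intensity rescaling); a constant ROI maps to level 1.
GLCMs count voxel pairs at one-voxel offset with both endpoints inside
the mask, symmetrized and normalized to unit mass; entropy is log base 2.
Runs are maximal same-level blocks along lattice lines, confined to the
mask (a run ends where the mask does), with lengths capped at the
shortest side of the mask's tight bounding box in voxels. GLRM features
use the `1/N_r` normalization with `N_r` the total run count. Each of
the 18 texture statistics is computed along the 13 unique-up-to-sign
3D lattice directions and summarized by the arithmetic mean and the
population SD over directions; a direction with no valid pair/run is
excluded, and a feature with no valid direction is missing.

## Difference features and missing data

`Diff1 = Mid − Pre`, `Diff2 = Post − Mid`, `Diff3 = Post − Pre`, per
feature cell; a missing operand makes the difference missing, so a
patient without a Mid scan contributes no Diff1/Diff2 cells but keeps
Diff3. Downstream statistics use pairwise deletion per feature; no
imputation is performed. The packaged roundness fixture stores its table
exactly as printed to 2 decimals; since its difference columns were
evidently computed from unrounded values, recomputed differences can
deviate from stored ones by up to 0.015 (one rounding step for the
difference plus one for each operand).

## Recurrence models

*Univariate screen.* The per-feature AUC is the Mann-Whitney probability
of correct ranking (ties counted ½). The p-value is the two-sided
Wilcoxon rank-sum test: for combined samples of ≤ 25 the exact
permutation distribution of the rank sum is computed by a subset-sum
dynamic program over doubled mid-ranks (ties handled exactly); beyond
that, the normal approximation with tie and continuity correction. The
screen applies the raw α = 0.05 threshold with no multiple-testing
correction, matching common practice in small exploratory cohorts; with
~770 candidate features, expect false positives among the significant
set, and treat it as a ranking, not an inference.

*Forward logistic selection.* Greedy forward selection by
likelihood-ratio test (χ², 1 df) against the current model, stopping when
the best candidate's p exceeds α. Fits use internally standardized
features and a small ridge penalty (inverse strength C = 1000) so
perfectly separating features — which the headline predictor is — retain
finite coefficients; collinear columns are dropped. The reported AUC is
in-sample, computed from the final model's fitted probabilities; each
selected feature is annotated with its point-biserial correlation to the
label. The candidate pool defaults to all features.

*Kernel-density naive Bayes.* Class priors are training-fold class
frequencies; each feature's class-conditional density is a Gaussian KDE
with Silverman bandwidth `h = 0.9·min(sd, IQR/1.34)·n^{−1/5}`, floored at
10⁻³ of the data range so degenerate samples still yield a proper
density. Posteriors are computed in log space; if the likelihood
underflows in both classes the posterior falls back to the priors.
LOOCV pools held-out posteriors across folds into a single ROC (per-fold
AUC is undefined at fold size 1); the feature-set search is greedy
forward on LOOCV AUC with ties broken toward smaller sets, then
lexicographically.

**Known limitation — pessimistic LOOCV null.** Under label permutation
the pooled-LOOCV AUC of this classifier is systematically *below* 0.5
(measured means ~0.27–0.40 for cohorts of 17–200): the held-out case is
absent from its own class's KDE, and the training priors shift against
its class, so its posterior is nudged away from its label; these shifts
are of the same order as the null score variability and decay only
slowly with n. The bias is conservative — the classifier under-reports,
never over-reports, performance on label-free data — and is negligible
whenever genuine separation dominates, but pooled null LOOCV AUCs should
not be expected to center on 0.5.

## Synthetic phantom cohorts

The generator emulates a serial-imaging cohort: by default 17 patients
with a 4/17 recurrence fraction (class counts exact: the first
⌈n·fraction⌉ patients are recurrent before a seeded shuffle), three
pre-aligned sessions per patient on the CT/PET grids above, and an
optional dropped Mid scan to exercise missing-data handling.

Tumors are lobulated ellipsoids: base semi-axes (16, 14, 12) mm jittered
±10%, randomly rotated, with the radius modulated by a band-limited
angular perturbation (8 plane waves of angular frequency 5–9 on the unit
direction sphere, unit RMS, clipped to ±1.2) whose amplitude `a ≤ 0.5`
keeps the shape star-shaped, hence 6-connected. The radius field is
rescaled by the spherical mean of `(1 + aP)³` so lobulation does not
change the enclosed volume, keeping shape drift and volume drift
independent.

The injected effect mirrors the serial-cohort observation the phantom
emulates: class-mean baseline roundness 0.71 (recurrent) / 0.76
(non-recurrent) with SD 0.04, and Pre→Post roundness drift **+0.08**
(recurrent, scatter SD 0.02) / **−0.06** (non-recurrent, scatter SD
0.045), with interim targets −0.01 / −0.06 from baseline. Per time
point, the lobulation amplitude is solved by bisection (tolerance 0.004)
so the *measured* roundness of the voxelized mask hits its target;
mechanically, recurrent tumors relax toward equal axes and shrink
isotropically, while non-recurrent tumors regress anisotropically along
one axis (z scaled by `f^0.7` for volume factor `f`) — a modeling choice
for the unquantified directional regression of responding tumors,
recorded per patient in the truth output. Both classes lose 35% volume
by the final time point (interim at the geometric midpoint).

Intensities: CT is a spatially correlated Gaussian field (mean 45 HU,
SD 12 HU, correlation length 4 mm) inside a body ellipse with air
outside and the tumor offset +15 HU; SUV is near-zero background plus
tumor uptake rising as the square root of boundary distance to a peak of
8, with 8% multiplicative noise clipped at the peak (saturation). The
phantom deliberately omits real anatomy, scanner point-spread and
reconstruction noise, and contouring variability — passing recovery
tests therefore demonstrates that the *pipeline* recovers injected
effects of realistic size, not that real cohorts carry such effects.

With these defaults, cohorts of n = 40 yield a univariate Diff3-roundness
AUC ≥ 0.9 in ≥ 9 of 10 seeds (the drift gap of 0.14 is several times the
injected scatter). All cohort content is a pure function of the spec,
whose single seed is fanned out per patient via seed sequences; the
pipeline fan-outs per stage the same way, so stages rerun independently.

## Problem sizes in the test suite

Deterministic checks run on the packaged 17-patient table or on masks of
≤ ~30³ voxels. Stochastic checks use: 10 cohorts of n = 40 (shape
features only) for drift recovery; 50 single-patient draws for the
sign of the non-recurrent drift; 20 permutation seeds at n = 40 for the
null control; and 10-seed tabular simulations (n = 40–60, 20–50 noise
features) for the selection procedures. Texture oracles enumerate pairs
and runs exhaustively on random masks of ≤ 6³ voxels in all 13
directions.
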