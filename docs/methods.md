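# Methods

## Coordinate and intensity conventions

Arrays are indexed `(y, x, z)`: axis 0 anterior–posterior, axis 1
left–right, axis 2 inferior–superior, so the axial plane spans (y, x) at
fixed z, the sagittal plane (y, z) at fixed x, and the coronal plane
(x, z) at fixed y. Gray levels are 1-based (`{1..Ng}`) throughout the
co-occurrence machinery; all user-facing voxel coordinates (lesion
centers, cluster peaks and centroids) are 0-based array indices.

## Quantization

Raw intensities are first standardized by a robust percentile-linear
rescale: the `[p_low, p_high]` percentile range inside the analysis mask
(defaults 1%/99%) maps linearly onto `[1, Qg]` (default `Qg = 256`) with
clipping. This is a deliberately simple stand-in for scanner intensity
standardization; it is invariant to global affine intensity changes and
robust to isolated outliers, but it does not correct spatially varying
bias fields — volumes should be bias-corrected upstream if that matters.

Quantization to the working level count `Ng` uses

    q(I) = round((I − 1)(Ng − 1)/(Qg − 1)) + 1 ,

which is monotone and endpoint-preserving (`1 → 1`, `Qg → Ng`). A form of
this map sometimes appears in the literature with the fraction inverted,
`(Qg − 1)/(Ng − 1)`; that variant sends `Qg` above `Ng` whenever
`Ng < Qg` and cannot be a map onto `{1..Ng}`, so the endpoint-consistent
form above is used. Rounding is half-away-from-zero, fixed so bin edges
do not depend on the platform's banker's rounding.

## Per-voxel co-occurrence matrices

**Offsets.** "Distance d" denotes the Chebyshev cube radius: the offset
set contains every nonzero integer displacement with max-norm ≤ d —
`(2d+1)³ − 1` offsets in 3D (26 at d = 1, 124 at d = 2) and
`(2d+1)² − 1` per plane (8 / 24). The set is closed under negation, so
every accumulated matrix is exactly symmetric and, after normalization, a
valid joint distribution over ordered gray-level pairs.

**Neighborhoods.** The full-3D variant uses the Euclidean lattice ball of
radius `R` around the voxel; membership is decided on integer squared
distances (`≤ R²`), never on floating-point radii. The three-planes
variant uses the in-plane lattice disk of radius `R` on each anatomical
plane through the voxel. Neighborhoods are clipped at the grid boundary
(no padding or mirroring); when a mask is supplied, out-of-mask voxels
are removed from every neighborhood and masked voxels are not evaluated.

**Counting rule.** A pair `(u, u + O)` contributes iff *both* endpoints
lie in the (clipped, masked) neighborhood; pairs straddling the boundary
are not counted. Each voxel's counts are summed over the whole offset set
and normalized by the total pair count. A voxel whose neighborhood yields
zero pairs (possible only under aggressive masking) is flagged invalid
and carries NaN through all downstream maps.

**Vectorization.** Rather than looping over voxels, the implementation
enumerates relative displacement pairs `(s, s + O)` that fit inside the
neighborhood shape once, and accumulates each pair's contribution to all
voxels simultaneously with shifted-array indexing and a single bincount.
This is algebraically identical to the per-voxel definition (the tests
verify equality against exhaustive enumeration entry-for-entry) and makes
whole-volume maps at 32³–128³ practical on one CPU.

**Plane averaging.** For the three-planes method each plane's matrix is
normalized independently and the *features* are averaged across planes
(never the matrices): averaging normalized matrices would let planes with
more pairs dominate, and feature averaging is what makes the method
sensitive to edges — an edge lies within at least one plane, where the
local matrices on either side are maximally different. A voxel is valid
for the three-planes method only if all three planes are non-degenerate.

## Texture features

Eight features of the normalized matrix `p(i, j)` are computed (see the
README for formulas): autocorrelation, homogeneity, energy, correlation,
dissimilarity, sum-of-squares variance, sum average, sum entropy.
Conventions:

* homogeneity uses the inverse-difference-moment kernel
  `1/(1 + (i − j)²)`; the `1/(1 + |i − j|)` variant is available via
  `homogeneity_form="abs"` since both circulate under this name;
* sum entropy uses the natural logarithm by default (`log_base`
  switchable), with `0·log 0 ≡ 0`;
* correlation on a matrix with zero marginal variance is defined as 0
  rather than NaN: a constant neighborhood carries no correlation signal,
  and a finite value keeps the voxel usable downstream;
* the variance feature centers on the row-marginal mean `μ_x` (equal to
  `μ_y` on these symmetric matrices).

## Voxelwise statistics

Per voxel, a linear model `value ~ intercept + group + covariates` is fit
by least squares (QR factorization shared across voxels) and the group
effect is tested with the extra-sum-of-squares F statistic against the
covariate-only reduced model, df `(g − 1, n − g − c)`. An F-test is used
instead of a t-test so texture increases and decreases are treated
symmetrically and ≥3 groups work unchanged. Covariates are mean-centered
for conditioning; sex-type covariates should be coded numerically (0/1).
Voxels invalid in any subject, or with a constant response, are excluded
from the analysis and the correction.

Multiple comparisons: Benjamini–Hochberg step-up over all analyzed
voxels, thresholding the adjusted value at `q` (0.05 by default; 0.01
with a 10-voxel extent filter is the stricter preset for whole-brain
analyses). Cluster extent uses 26-connectivity by default (6/18
selectable). No smoothing of texture maps and no global intensity
normalization is applied at this stage.

Numerical note: residual sums of squares are obtained by subtracting the
projected norm from the total norm, which loses relative (not absolute)
precision when F ≈ 0; tests compare F to the t² identity with a 1e-10
absolute floor for this reason.

## Synthetic cohort

The generator emulates an artificial-effects validation: backgrounds are
Gaussian white noise smoothed with an isotropic kernel (default scale 2
voxels) and affinely rescaled to an exact sample mean and SD (defaults
128 and 24 on a 0–255-like scale — T1-ish contrast and a smoothness scale
of the order of a normalized MRI's effective resolution). Lesions are
additive bumps `sign · A · SD_bg · exp(−r²/2σ²)` truncated at a hard
support radius (defaults σ = 2, radius 4, A = 3), which makes the
ground-truth mask crisp and the overlap metrics unambiguous. The demo
design uses 8 interior lesions — 4 hyper-, 4 hypo-intense on a 2×2×2
layout — in 30 + 30 subjects at 32³, sizes chosen so the full study runs
in seconds-to-minutes on one CPU while each lesion (≈257 voxels) spans
many neighborhood radii.

The lesioned arm is seed-matched to the control arm: subject *i* in both
arms shares the same background, mirroring designs where artifacts are
implanted into the images of the same healthy subjects. Consequently the
two arms differ *only* inside the lesion masks, and the generator's
effect size dial is exactly the lesion amplitude.

What this cohort does **not** emulate: anatomy (no gray/white-matter
geometry or tissue boundaries), bias fields, Rician noise, registration
error, or between-subject anatomical variability. Passing the synthetic
validation therefore demonstrates that the pipeline's machinery is
correct and sensitive to localized textural change of the modeled kind;
it does not by itself establish performance on real MRI, where overlap
scores will generally be lower.

## Evaluation metrics

Aggregate union overlap, false-negative and false-positive errors are
computed from voxel counts pooled over lesions (not averaged per-lesion
ratios); the per-lesion table also reports individual ratios with their
mean ± SD so either convention can be compared. Detected voxels are
assigned to lesions by containment, then by connected component (nearest
lesion center on ties); components touching no lesion are counted in the
false-positive numerator and all detection denominators and reported
separately as unassigned. An empty detection map yields detection 0%,
FN = 1 and an undefined (NaN) FP. Two-sample comparisons of measurement
populations (e.g. UO at Q = 8 vs Q = 16) use the pooled-variance
two-tailed t-test, with a Welch option.

## Default parameters

| parameter | default | notes |
|---|---|---|
| gray levels Q (`Ng`) | 8 | 8 or 16 are the practical choices; small neighborhoods cannot populate many levels |
| neighborhood radius R | 2 voxels | 1–3 is the useful range: large enough to form patterns, small enough to stay local |
| offset distance d | 1 | must be ≤ 2R for pairs to exist; 1–3 useful |
| method | top3d | more edge-sensitive and ~5× fewer offsets at d = 2 than full3d |
| FDR q | 0.05 | 0.01 + extent 10 for stricter whole-brain analyses |
| connectivity | 26 | cluster-extent filtering |

## Known limitations

Whole-volume maps at clinical resolution (≈180³) with Q = 16 and d = 2
require a few GB of intermediate count arrays; process within a brain
mask or in slabs if memory is tight. The intensity standardization is
global-affine only. The statistics stage assumes voxelwise Gaussian
errors and homoscedastic groups; no random-field or permutation
inference is provided.
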