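# Methods

## Data model and conventions

All images are `VoxelGrid`s: a 3-D scalar array with spacing (mm), origin
(world mm of voxel (0,0,0) centre) and an orthonormal direction matrix
(identity for all synthetic data). Indices are 0-based and voxel-centred,
ordered (i, j, k) with i fastest along world x. Transforms are world-space
affines `x ↦ Mx + t`; resampling uses the pull convention (the output value
at reference point x is the moving image at T(x)), linear interpolation for
intensities, nearest-neighbour for masks, fill value 0 outside the moving
domain (both modalities are near-zero outside the specimen). Volumes are
stored as NIfTI-1; float64 payloads round-trip bit-exactly, geometry to the
precision of the float32 NIfTI header.

## Synthetic study generator

The generator emulates the statistical structure the analysis assumes, not
scanner physics. Geometry: an ellipsoidal condylar cap (semi-axes 8.5, 6.8,
8.5 mm; the 0.8 y-aspect breaks rotational symmetry about the long axis,
without which a rotational misalignment about that axis would be
unidentifiable) on a cylindrical shaft (radius 5.5 mm, length 22 mm), with
a cortical shell 1.6 mm thick (distance transform from the bone surface).

* **Porosity** φ: shell ≈ φ_c = 0.035, core ≈ φ_t = 0.793 (literature
  values for cortical vs trabecular porosity), plus band-limited Gaussian
  variation (SD 0.06, smoothness 1.5 mm), clipped to [0, 1].
* **BMD** = ρ_max(1 − c·φ) + N(0, 25²) mg HA/cm³ with ρ_max = 1400,
  coupling c = 0.4. The homogenised two-compartment bone (no sub-voxel
  trabecular mesh) motivates the moderate coupling: it keeps the
  trabecular-core grey plausible for a densified condyle and inside the
  capture range of a contrast-based threshold, which on real CT works
  because trabecular bone is a bright mesh at 0.27 mm resolution.
* **CT**: grey = g0 + g1·BMD + N(0, 10²), g0 = 40, g1 = 1.8 grey per
  mg/cm³; soft-tissue background 60; four calibration rods (radius 1.5 mm,
  densities 0/100/400/800 mg HA/cm³) in the field-of-view corners. Grid
  96³ at 0.273 × 0.273 × 0.4 mm.
* **MR**: per voxel S(TE) = A_BW(1−φ)e^(−TE/T2*_BW) + A_PW·φ·e^(−TE/T2*_PW)
  with TE = 0.04 / 2.52 ms, T2*_BW = 0.39 ms, T2*_PW = 10 ms (the reported
  acquisition parameters include no relaxation constants; these are
  literature-typical magnitudes with PW ≫ BW, and are config values).
  Evaluated on the CT grid, resampled onto the 64³ / 0.66 mm isotropic MR
  grid through the misalignment transform, then additive Gaussian noise
  (SD 0.02 for unit proton-density amplitudes; a Rician option exists —
  at this SNR the difference is second order and Gaussian keeps the
  analytic attenuation formulas exact).
* **Misalignment**: 5° rotation about z through the volume centre plus a
  (3.2, −1.5, 0.8) mm translation; the ground-truth aligning transform is
  its inverse. Default study shape: 6 horses × {LF, RF, LH, RH}, per-limb
  spec overrides (including an `excluded` flag) and seeds spawned
  deterministically from the study seed.

What the generator does **not** emulate: k-space/radial readout, partial
volume at sub-voxel trabeculae, fat signal, beam hardening, biological
covariates. Consequently the synthetic voxel-wise |r| between BMD and PI is
high (≈ 0.95–0.99) rather than the ≈ 0.3 of real condyles, where most
decorrelation comes from structure the generator omits. Recovery tests
therefore compare estimates to the generator's own ground truth, not to the
published correlation strength.

## Pipeline stages

**Calibration.** OLS of insert density on per-insert mean grey (exact line
for two inserts); applying the model is the affine map a·grey + b per
voxel. Negative calibrated BMD is retained by default — clamping would bias
the voxel-wise regression. Insert ROIs are explicit inputs; a convenience
detector for the synthetic rod layout exists but clinical phantom masks
should be supplied.

**PI map.** 100·echo2/echo1 where echo1 exceeds a floor (default 5× the
background noise SD estimated from the eight corner patches of the short
echo); other voxels are NaN and excluded via the validity mask. Values
above 100 % are kept and only reported in diagnostics.

**Segmentation.** Median filter over a spherical neighbourhood (radius 2
voxels, 33 samples; truncated at edges, even counts averaged — the numpy
median convention), then the Bernsen rule: per voxel, with lo/hi the
min/max in a centred 50-voxel cubic window (replicate padding preserves
truncated-window semantics), high-contrast voxels (hi−lo ≥ threshold) are
foreground when ≥ (hi+lo)/2; low-contrast regions are foreground when their
midgrey strictly exceeds the global mid-grey (strictness makes a uniform
image empty). The default contrast threshold is half the robust global
range (percentiles 0.5–99.5), which sits between the cortical/trabecular
contrast and the bone/background contrast; it is a free parameter for real
data. Largest 26-connected component isolates the bone (ties break to the
lowest flat index); an axis-aligned cut at a stated fraction of the
long-axis extent isolates the condyle, the reproducible stand-in for
interactive diaphysis removal. The distal end is chosen automatically as
the bulkier end (parameterisable).

**Registration.** Fixed = CT, moving = PI map (default; echo1 — higher SNR
— is an option and recovers anisotropic scale about 3× better). Stage 1:
multi-resolution rigid capture (SimpleITK, Mattes MI, 32 bins, shrink
4/2/1, regular-step gradient descent, 25 % voxel sampling with a fixed
seed — deterministic). Stage 2: full-resolution Powell refinement of all 12
affine parameters (translation, Euler angles, scales, shears about the
fixed-image centre) maximising the plain joint-histogram MI in bits. Two
numerical details matter: histogram bin edges are fixed from the
untransformed images (data-dependent edges make the metric jagged in the
transform), and the metric is restricted to a dilated foreground mask of
the fixed image (the uniform background otherwise flattens the landscape
and, with Parzen-window metrics, creates a spurious optimum ~20 % away in
scale). Recovery at study conditions: translation ≤ 0.1 mm, rotation
≤ 0.4°, scale error ≤ 2×10⁻⁴ for the rigid truth; ≤ 1° / ≤ 1.8 % (PI) or
≤ 0.5 % (echo1) when the truth includes 2 % anisotropic scale.

**Statistics.** Per specimen, OLS of PI (%) on BMD over valid ROI voxels:
slope = Sxy/Sxx, SE(slope) = √(RSS/(n−2)/Sxx), r = Sxy/√(SxxSyy), two-
tailed p from t = r√((n−2)/(1−r²)) on n−2 df (identical for slope and r in
simple OLS). Strength labels are the Evans bands on |r| rounded
half-away-from-zero to 2 d.p. Group summaries use the n−1 SD and
SE = SD/√n. Normality: Jarque–Bera, JB = n/6(S² + (K−3)²/4) from 1/n
central moments, p from χ²₂. Group comparison: two-sample t-test, Student
pooled-variance by default with Welch available. Groups: forelimbs
{LF, RF}, hindlimbs {LH, RH}, left {LF, LH}, right {RF, RH}; excluded limbs
are carried as explicit table rows and dropped from analysis. BMD units
(mg HA/cm³) are metadata, not baked into formulas.

## The packaged per-limb table

`utepi/data/table1.csv` transcribes the published per-limb slope/SE/r table
(23 analyzable limbs; one forelimb excluded for metallic implants). Its
values are printed at 2 d.p. (r) and 2 significant figures (slopes), which
bounds how precisely the published summary statistics can be reproduced:
the group means of r agree to half a unit in the last printed digit, while
the mean slope of the rounded values is −0.00834 against the published
−0.0084 (computed from unrounded data), i.e. agreement to one unit in the
last digit. The published fore-vs-hind p = 0.036 is likewise not
recoverable from rounded r values (recomputation gives p ≈ 0.046); the
qualitative pattern — fore vs hind significant at 0.05, the other three
comparisons not — is reproduced exactly.

## Problem sizes and budgets

Unit tests run on a geometrically half-scaled phantom (48³ CT / 32³ MR,
bone shrunk proportionally) with tolerances scaled to the coarser voxel;
the acceptance suite and `scripts/acceptance.py` use the study's native
sizes (6 horses × 4 limbs, CT 96³, MR 64³), with registration recovery
evaluated on two specimens and the noise sweep on one 4-limb horse at MR
noise SD 0.02/0.08/0.16. A full acceptance run takes a few minutes on one
CPU.

## Known limitations

* The homogenised bone model cannot exhibit the weak correlations of real
  condyles (see above); absolute slope magnitudes also differ from
  published values (PI responds ≈ 80 % per unit φ here, concentrated over
  a narrower BMD range).
* PI near the shell/core interface is biased at MR resolution because the
  ratio of interpolated echoes is not the interpolated ratio; comparisons
  against ideal PI are meaningful only a few voxels away from interfaces.
* Bernsen thresholding assumes the within-bone contrast is below the
  bone/background contrast; with the default auto-threshold this holds for
  the generator and for densified condyles, but the contrast parameter
  must be set for other anatomies.
* Registration assumes the initial misalignment is within the rigid
  stage's capture range (tested to ~5 mm / 5°); larger offsets need an
  explicit initial transform, standing in for the manual rigid
  pre-alignment of clinical workflows.
* No deformable registration, no cortical/trabecular sub-segmentation, no
  multiple-comparison correction across the four group tests.
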