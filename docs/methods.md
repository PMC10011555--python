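# Methods

`fiberorient3d` maps 3D myelinated-fiber orientations in fluorescence
microscopy volumes by multiscale Hessian (Frangi-type) enhancement of
tubular structures, and aggregates the voxel-wise orientations into
spherical-harmonics orientation distribution functions (ODFs) on
super-voxel grids. This note records the model, the numerical choices,
and what the synthetic phantoms do and do not establish.

## Enhancement model

At scale σ the volume is convolved with an isotropic Gaussian and the
six unique second derivatives are computed by separable
Gaussian-derivative kernels, truncated at 4σ, with the image held in
32-bit floats. Derivatives are scale-normalized with one factor of σ
per derivative order (σ² on the Hessian), which makes the response of
tubes of different calibre comparable inside the multiscale maximum —
without it, fine detail would systematically dominate. Per voxel the
Hessian eigenvalues are sorted by magnitude, |λ1| ≤ |λ2| ≤ |λ3|, and
combined into

- blobness `R_B = |λ1| / sqrt(|λ2 λ3|)`,
- in-plane aspect ratio `R_A = |λ2| / |λ3|`,
- structureness `S = sqrt(λ1² + λ2² + λ3²)` (Frobenius norm),

and the vesselness score

```
V(σ) = exp(-R_B²/2β²) · (1 − exp(-R_A²/2α²)) · (1 − exp(-S²/2γ²))
```

for λ2 ≤ 0 and λ3 ≤ 0 (bright tubes on a dark background), and V = 0
otherwise. The final map is the voxel-wise maximum over scales; the
fiber orientation is the dominant eigenvector v1 (minimum-curvature
direction) at the winning scale. When scales tie, the smallest scale
wins — a reproducibility convention, nothing more.

Parameters and defaults:

- `α = 0.001` — the filter responds to anything remotely elongated;
  plates are only suppressed when R_A is essentially zero.
- `β = 1` — moderate blob penalty (isotropic structures are attenuated
  by `exp(-1/2) ≈ 0.61` relative to ideal tubes).
- `γ` — auto-set to half the maximum structureness of the processed
  (sub-)volume, per scale. With that choice the best voxel's
  structureness term is exactly `1 − e⁻² ≈ 0.865`. An all-background
  chunk (S ≡ 0) falls back to γ = 1 and a zero map.
- scales — chosen from the calibre rule below; the reference
  configuration for 4–6 µm fibers is {1, 1.25, 1.5} µm.

Numerical details: eigendecomposition is restricted to voxels whose
structureness exceeds 1% of its reference level (2γ); below it the
structureness factor alone bounds V by ~2·10⁻⁴ and the voxel is
reported as exactly zero. Degenerate voxels with |λ3| = 0 take
R_B = 0, R_A = 1 so no NaNs propagate (S = 0 already forces V → 0).
Eigenvectors are sign-normalized to the z ≥ 0 hemisphere (ties broken
y ≥ 0, then x ≥ 0); orientations are axial, so the convention only
fixes serialization.

## Scale-to-calibre rule

The working rule is σ_opt = radius/2, i.e. scale = diameter/4: 1, 1.25
and 1.5 µm scales are matched to 4, 5 and 6 µm fibers. The
characterization sweep (`tuning.py`) reproduces it on a noiseless
cylinder: at small scale-to-radius ratios the kernel acts like a delta
and the response collapses onto a spurious ridge at the fiber edge; at
large ratios the structure is blurred wide. Preservation of the
original intensity and cross-sectional size is scored on the *raw*
curvature response — the Hessian with the σ² compensation divided out,
under a single sweep-wide auto γ — read at the axis midpoint, with the
profile FWHM around the axis. The distinction matters: σ-compensation
is a cross-scale comparability device, while "how much of the original
contrast survives" is a fixed-unit question; the σ²-compensated axis
response peaks near σ ≈ 0.7·radius instead (a continuum quadrature of
the smoothed-disc curvature confirms both numbers), and only the raw
response reproduces the half-radius rule and hence the diameter/4
mapping used throughout.

The dual sweep (fixed 1.25 µm scale, diameters 3–7 µm) scores each
diameter by its *preserved fraction* — the axis response at the fixed
scale relative to that calibre's own best attainable response over a
scale sweep. Raw amplitudes of different calibres scale as 1/r² and
cannot be compared directly. The diameter sweep runs at 2 px/µm with
the ceiling search restricted to σ ≥ 0.7 voxel: below that the sampled
derivative kernels degenerate into noisy finite differences.

## Preprocessing

Point-scanning microscopes resolve worse axially than laterally; the
compensation blurs each XY plane with a Gaussian of variance
σ_PSFz² − σ_PSFi² (i = x, y), converting FWHM to σ with
2·sqrt(2 ln 2) ≈ 2.3548, then downsamples laterally to isotropic 1 µm
voxels with linear interpolation (order 1: downsampling after a blur,
higher orders only add ringing). Resampling uses an affine map with
the exact target spacing rather than `zoom`, which rounds the scale to
an integer-shape ratio and distorts the voxel size on small volumes.
Both stages are optional (deconvolved or already-isotropic data skips
them). Defaults use the reference PSF FWHM of 0.692 × 0.692 × 2.612 µm.

## Segmentation

Fiber voxels: Li's minimum cross-entropy threshold on the float
vesselness map (no requantization). Cell bodies: Yen's
maximum-correlation threshold on the soma channel, subtracted from the
fiber mask; lipofuscin autofluorescence makes somata bright and
compact there. Thresholds adapt per processed chunk by default,
matching the streaming design; `--global-normalization` computes γ per
scale and the thresholds volume-wide in a first pass, making chunked
output bitwise-identical on chunk cores to a whole-volume run (the
per-chunk default trades seams for a single pass).

## ODF estimation

Orientations are axial, so each contributes as an axis and only even
spherical-harmonic orders carry information. Within each cubic
super-voxel (partial edge compartments retained, with their
orientation count K recorded) the coefficients of the orientation
distribution are computed analytically as the mean of the real
symmetric basis functions over the K orientations — each orientation a
Dirac delta on the sphere, no directional histogram in between. The
expansion is truncated at lmax = 6 (28 coefficients); c00 is
1/(2·sqrt(π)) for every populated compartment, and empty compartments
are flagged and zeroed. The real basis (cos/sin azimuth factors with
orthonormal normalization) is the only self-consistent resolution of
the complex-vs-real bookkeeping, and it serializes directly to a 4D
NIfTI with MRtrix-compatible ordering (ascending even l, m from −l to
l) and the super-voxel size as voxel spacing. Coefficients are stored
raw, with no per-compartment amplitude normalization.

## Validation protocol

Accuracy is quantified without ground-truth segmentation: 75 × 75 × 15
µm patches are sampled at random (uniform corners, independent random
flips along each axis), extended by a margin of
`ceil(diag·(1 − cos 45°)/2) + ceil(4σ_max)` voxels, rotated about the
z axis (in-plane) and the x axis (out-of-plane) over ±45° in 5° steps
(18 test rotations per axis) with prefiltered cubic-spline
interpolation, and re-analyzed at scales {1, 1.25, 1.5} µm. Azimuth
φ_xy and elevation θ_zy are binned into 180 one-degree bins; the
rotated patch's distribution is compared with the reference
distribution shifted by the applied angle on the 180°-periodic axial
circle, via the circular-median distance (exhaustive scan over bin
centers, ties toward the smallest angle — plain medians break at the
±90° wrap) and the Bhattacharyya coefficient Σ√(p·q). Patches whose
fiber fraction drops below 1% at any tested rotation are excluded
entirely, so every rotation aggregates the same patches.

Protocol details that matter:

- Azimuth is measured on the x ≥ 0 axial representative (range
  [−90°, 90°)); elevation on the y ≥ 0 representative (the θ_zy
  sense). With an x ≥ 0 fold the elevation sign would flip across the
  ±90° azimuth boundary and under axis flips, breaking the 1D
  reference shift for out-of-plane rotations.
- Rotation fill-in is excluded by a rotated validity mask (zero-filled
  intensities would create spurious edges), eroded by the filter
  support; the reference histogram is restricted to the evaluated
  region mapped back into the unrotated frame, so both distributions
  sample the same fiber segments.
- Angular statistics are taken on mask-interior voxels (one-voxel
  erosion). At the Li mask rim the dominant eigenvector is
  ill-conditioned — the smoothing halo makes the axis and the
  edge-ring tangent nearly degenerate (measured: ~23° 90th-percentile
  azimuth error at the rim vs 1.3° in the interior). The 1% fiber
  fraction criterion still uses the full mask.

## Synthetic phantoms

Solids (cylinders, spheres, slabs, crossings, multi-fiber stacks) are
rasterized from signed distance functions with 4×4×4 supersampled
anti-aliased boundaries (an even factor keeps sample points off voxel
centers, where axis-aligned surfaces of integer-sized solids would be
hit exactly); gray levels default to 200/10 on an 8-bit-like scale,
noiseless, with optional additive Gaussian noise as the only noise
model. Validation stacks default to 16 straight fibers of 5 µm
diameter in a 160 × 160 × 80 µm volume with azimuths ~ N(90°, 5°):
the 1D elevation correction is exact only for fibers orthogonal to the
x rotation axis (a fiber at azimuth φ rotated by ρ acquires elevation
asin(sin φ · sin ρ), a 3.5° bias already at φ = 110°, ρ = 45°), so the
stand-in keeps its tracts within ~10° of y — the same coherent-tract
regime in which the out-of-plane claim is meaningful for real data.

What passing phantoms shows: the geometry of the whole chain —
enhancement, orientation extraction, masking, angular statistics, the
rotation harness — is correct to within interpolation tolerances.
What it does not show: robustness to autofluorescence texture, shot
noise, illumination artifacts, or fiber curvature and branching; real
tissue has all of these, and the phantom bounds should be read as the
noise-free limit of the protocol.

## Chunked processing

Volumes are processed in near-cubic cores that tile the volume exactly
once, each read with a margin of ceil(4σ_max) voxels (volume borders
half-sample-reflected, matching the filter's own border mode) and
sized so one extended float32 chunk fits the memory budget. Because
the margin covers the truncated kernel support, chunk cores are exact;
only the per-chunk γ and thresholds differ from a whole-volume run
unless global normalization is on. Peak working memory then follows
the chunk budget, not the volume size.

## Problem sizes used in the checks

The automated checks run on desk-scale inputs chosen to keep the
discretization honest: the scale sweep uses a radius-1 µm cylinder at
10 px/µm (aspect ratio 12), the diameter sweep 3–7 µm cylinders at
2 px/µm, and the rotation protocol 3–5 stacks with 2–3 patches each.
Larger inputs change none of the logic — only the statistics tighten.
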