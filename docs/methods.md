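# Methods

This note documents the models, parameter choices and numerical decisions
behind `choromet`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## The measurement problem

The package quantifies posterior-segment changes between paired OCT
sessions of the same eye: mean retinal thickness (ILM to mid-RPE) and mean
choroidal thickness (mid-RPE to choroid–scleral interface, CSI) over 1 mm
and 3 mm circles centered on the foveal pit, plus the radii of best-fit
circles to the mid-RPE along four en-face directions. The choroid is the
primary endpoint: it is perfused, autonomically innervated tissue whose
thickness responds within minutes to vascular tone, so a paired
baseline/stressor design with ~µm-scale sensitivity is required. Because
expected effects (a few µm) are far below the axial pixel pitch, every
stage is designed around sub-pixel accuracy and paired-bias cancellation.

## Synthetic eye phantom

`synthetic_data.generate_eye` builds continuous ground-truth surfaces on a
(B-scan, A-scan) grid:

* **mid-RPE**: a sphere cap of radius `posterior_radius_mm` (default 19 mm,
  the scale of measured posterior-pole radii) centered en-face at the fovea,
  with its apex `rpe_depth_at_fovea_mm` (1.3 mm) below the image top.
* **ILM**: one retina thickness above the mid-RPE (default 315 µm), minus a
  Gaussian foveal pit (depth 100 µm, radius 0.6 mm — chosen so the average
  retina over the central 1 mm disc lands near 245 µm) and plus a shallower
  optic-disc cup (80 µm) 4 mm nasal of the fovea.
* **CSI**: one choroid thickness (default 283 µm) below the mid-RPE.
* Both thickness fields carry a small seeded smooth undulation (±4 µm) so
  surfaces are not analytically perfect.

Anatomy that is fixed per eye — the optic-disc footprint, an en-face
choroidal-texture field (vascular surrogate), and ten radial retinal
vessels (150 µm caliber) fanning out from the disc — is stored with the
ground truth and moves rigidly with the geometry, so two sessions of one
eye differ only in speckle and in the applied effect. The vessel shadows
and disc are not cosmetic: they are the rotational anchors that make rigid
registration identifiable, exactly as retinal vasculature is in real scans.

**Rendering.** Each A-scan column is a stack of sigmoid band transitions
(edge width 0.75 px) between reflectivities vitreous 0.05, retina 0.40, RPE
0.95 (30 µm band), choroid 0.30, sclera 0.12, so boundary positions survive
discrete sampling at sub-pixel precision. Attenuation is exponential in
*tissue* depth (`exp(−µ·max(0, z − ILM))`, default µ = 0.5 mm⁻¹): the
vitreous is optically transparent, and making attenuation start at the ILM
keeps band contrast physically consistent when geometry moves axially.
Speckle is unit-mean gamma multiplicative noise. The per-cell shape (4,
matching 4-frame compounding of exponential intensity speckle) is scaled by
the number of optical resolution cells (20 µm lateral × 8 µm axial) each
voxel integrates, so the reduced 64×64×256 default grid over the full
12×12×4.5 mm extents shows the smoother effective speckle a real
downsampled scan would (per-voxel SD ≈ 11 % of signal), while a
full-resolution 512×512×1920 render reproduces near-raw speckle.

**Stress effect.** `apply_stress_effect` displaces the CSI posteriorly by
`delta_ct_um` (the retina untouched) and then moves the whole geometry by a
small rigid transform — (dz, db, da) translation plus a torsion about the
depth axis — emulating between-session repositioning. Cohort simulations
draw ΔCT per subject from Normal(3.3 µm, 6.1 µm), the effect scale of the
choroid's stress response over a 3 mm circle.

**RR series.** First-order autoregressive gaussian intervals with the
stationary SD requested. RMSSD of an AR(1) process is
`sd·sqrt(2(1−φ))`, so the default φ = 0.7 keeps RMSSD below SDRR as in
real recordings. Default study conditions: baseline mean RR 779 ms
(≈77 bpm) with SD 48 ms (RMSSD ≈ 37 ms); stressor mean RR 692 ms (≈87 bpm)
with SD 33 ms (RMSSD ≈ 25 ms).

## Enhancement

Perona–Malik diffusion (4-neighbor, conduction `exp(−(g/κ)²)`, reflective
borders) uses κ = 0.03 intensity units, λ = 0.2, 20 iterations: κ sits
between the speckle gradient scale (~0.02/px after resolution-cell
averaging) and layer-edge gradients (~0.1–0.3/px), which denoises bands
while pinning boundaries. The conservative scheme preserves the image mean
to round-off and obeys the discrete maximum principle for λ ≤ 0.25.

Adaptive compensation divides each column's contrast-raised signal by twice
its depth suffix sum (exponent n = 2, final 1/n root), equalizing the
energy budget down the column; the deepest nonzero sample maps to 0.5
before the root, and the amplification of the noise floor near the bottom
of the scan is a known artifact that the segmenter's anatomical band
bounds keep out of reach.

## Segmentation

A classical dynamic-programming boundary search stands in for a trained
network segmenter, with the identical output contract (per-A-scan ILM,
mid-RPE, CSI depths plus validity; externally produced surface TSVs can be
dropped in). Per B-scan:

1. **mid-RPE** first — the minimum-cost path through the normalized
   negative-intensity image (the RPE is the brightest, most reliable
   reflector);
2. **ILM** — strongest dark-to-bright axial gradient above the retinal
   band (mid-RPE minus at least 120 µm);
3. **CSI** — strongest bright-to-dark transition between 80 and 700 µm
   below the mid-RPE.

Paths step at most 5 px per A-scan with a penalty of 0.02 (normalized cost
units) per pixel of step; the step bound corresponds to the steepest
posterior-pole slope at the ~10:1 transverse-to-axial pitch ratio of both
the full and the reduced grid. Integer paths get parabolic sub-pixel
refinement on the data cost. Surfaces are median-smoothed across B-scans
(window 3); B-scans with >20 % invalid A-scans are interpolated from
neighbors and flagged, and a volume with >20 % invalid A-scans overall is
flagged poor quality (the scan-substitution rule uses this flag). Layer
masks derive from the surfaces by the half-open rule `top ≤ z < bottom`, so
truth and measured masks are scored by Dice on identical conventions.

## Registration and symmetric resampling

Between-session motion of a head-rest-stabilized eye is en-face shift,
axial shift and a small torsion about the depth axis, so four parameters
are estimated; out-of-plane tilts are fixed at zero because on layered,
posteriorly curved anatomy they are near-degenerate with the torsion's
layer-tilt signature and letting them float destabilizes the fit. Stages:

1. 2D registration of depth-mean en-face projections (angle scan with
   FFT cross-correlation for the shift at each angle, then least squares
   with cubic interpolation — linear interpolation's offset-dependent
   smoothing measurably biases the angle);
2. a 1-D axial-offset scan (±4 px);
3. a joint polish of the three translations by Levenberg–Marquardt on
   cubic-spline-interpolated interior voxel residuals.

Recovered accuracy on independently rendered moved geometry is ~0.2 px
translation and ~0.2° rotation at the reduced grid.

For the paired analysis both sessions are resampled once each through the
half transforms S and S⁻¹ (S∘S = estimated motion) onto a common mid-space
grid. One interpolation pass per session with mirrored fractional offsets
makes the (small but measurable) interpolation-smoothing bias common-mode,
so it cancels in paired thickness differences; resampling uses a cubic
B-spline kernel, clipped to the input intensity range. Repeatability
(Bland–Altman) compares the two raw baseline scans without any resampling.

## Morphometry

Thickness is strictly axial: boundary depth difference × axial pitch. ROI
membership uses Bennett-scaled physical distance
(`ratio = 3.382 × 0.013062 × (axial length − 1.82)` applied to the nominal
transverse calibration) with strict inequality against the circle radius.
The fovea is the argmax of the ILM depth after subtracting a broad gaussian
baseline (σ = 8 px ≈ 1.5 mm): the pit rides on the curved posterior pole,
and without detrending the sphere sag would out-deepen the pit away from
the center. The search covers the central half of the grid; ties break
toward the grid center.

Curvature radii sample the mid-RPE by bilinear interpolation at
1-nominal-pixel steps along en-face lines through the fovea at 0°, 45°,
90°, 135° (counterclockwise, 0° = the horizontal B-scan direction), keep
points within the direction's horizontal window (6 mm for the obliques,
5 mm vertical, 5 mm temporal / 3 mm nasal horizontal — the asymmetric
window avoids the optic disc), and fit a circle in the (arc-position,
depth) plane in physical mm: Kåsa algebraic fit plus one Gauss–Newton
geometric refinement. Samples with depth range below 10⁻⁶ mm are reported
as infinite radius and excluded from cohort statistics.

## HRV

Windows take beats whose end-time lies in `(event − 20 s, event]`,
end-anchored at each OCT acquisition's end. Mean HR is the time-weighted
`60000·n/Σrr` (equivalent to 60000 over the mean interval) rather than the
mean of instantaneous rates — stable for short windows. RMSSD is
`sqrt(mean(diff(rr)²))`. No artifact rejection is applied by default; an
optional running-median beat filter exists but is off, matching a protocol
that excludes bad recordings rather than editing beats.

## Statistics

Shapiro–Wilk at α = 0.05 on the paired differences gates paired t vs
Wilcoxon signed-rank (zero differences excluded; exact null for n ≤ 25,
normal approximation beyond). Correlations gate Pearson vs Spearman on
both variables' normality. Bland–Altman uses scan2 − scan1 differences and
the conventional 1.96 multiplier with the sample SD. No multiple-testing
correction is applied across the eight morphometric endpoints; reports
state per-endpoint p-values at α = 0.05. Identical paired vectors are a
degenerate case reported as p = 1 rather than an error.

## Problem sizes and determinism

The default test geometry is 64×64×256 voxels over the full physical
extents, chosen so a complete synthetic subject (three renders,
enhancement, registration, segmentation, morphometry) processes in
seconds and a 33-subject cohort in minutes on one core; the full
acquisition geometry is configuration only. Every simulation is a pure
function of (config, seed); re-running a cohort with the same seed
reproduces every report number bit-identically.

## What the synthetic experiments do and do not show

The phantom reproduces the geometry, banding, attenuation, speckle
statistics, anatomy-anchored registration landmarks and effect structure
the analysis relies on, so passing tests demonstrate that the chain is
unbiased and sensitive at the µm scale *under the generative model*. They
do not demonstrate robustness to real-data phenomena the generator omits:
intra-scan motion artifacts, vessel-level choroidal texture and shadowing
heterogeneity, pathology, segmentation-confusing epiretinal features, or
device-specific signal-strength variation. The CSI in particular is a
low-contrast boundary in vivo; the classical segmenter's Dice ≈ 0.98 on
synthetic data mirrors, but does not establish, network-level performance
on real B-scans.

## Known limitations

* Out-of-plane tilts are not estimated during registration; genuinely
  tilted acquisitions would leave a residual.
* "Middle of the RPE" is operationalized as the RPE band's intensity peak —
  a proxy that is exact for a symmetric band.
* The curvature fit works in the sampled line's (arc-position, depth)
  plane, not a true oblique 3D section.
* The 0° temporal/nasal window relies on the declared eye orientation;
  mislabeled laterality swaps the windows.
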