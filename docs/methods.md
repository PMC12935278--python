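# Methods

## Measurement model

A phase-sensitive spectral-domain OCT system reports, per pixel, the
phase difference `Δϕ` of two A-scans separated by `Δt`, which maps to an
axial displacement `Δz = λΔϕ/4π` and an instantaneous axial velocity
`v = λΔϕ/(4πΔt)`. Only the projection of the true velocity vector onto
the beam (optical) axis is observable. The acquisition is
stimulus-synchronous: at each lateral position one phase-difference pair
is triggered at a controlled stimulus phase; the trigger phase advances
by `Δφ = 2π/15` between snapshots so that N = 60 snapshots sample four
whole stimulus cycles. The trigger-phase wrap is computed in exact
rational cycle arithmetic, so snapshots completing whole cycles (e.g.
snapshot 16) carry a wrapped phase of exactly zero.

The complex tone at the stimulus frequency is recovered by the
correlation filter

```
v = (2/N) Σₖ vₖ exp(−i φ_c[k]) ,   φ_c[k] = (k−1)·Δφ
```

normalized so that `|v|` is the *peak* velocity amplitude (a noiseless
`vₖ = A cos(φ_c[k] + φ₀)` reconstructs exactly to `A e^{iφ₀}`; the peak
convention is a package choice — an RMS convention would differ by √2).
On the uniform multi-cycle grid the filter nulls DC and the second
harmonic exactly. The pair estimator attenuates a 1 kHz tone sampled
with Δt = 9 µs by `sinc(fΔt) > 0.9998`, so samples are treated as
instantaneous velocities. Phase differences are assumed pre-wrapped to
(−π, π]; amplitudes that would exceed this linear range trip a
saturation warning rather than being unwrapped.

## Orthogonal decomposition and its error budget

Three acquisitions with linearly independent unit axes (reference axis
`[0,0,1]`, the others expressed by polar angle θ from it and azimuth φ)
give `v = O⁻¹m`. The closed form
`det O = sinθ₁ sinθ₂ sin(φ₂−φ₁)` exposes the ill-conditioned
configurations; matrices with `|det| ≤ 1e−6` raise an error rather than
returning enormous amplification factors. The noise amplification
factors are the norms of the first two rows of `O⁻¹`; with the
reference row `[0,0,1]` the third row of `O⁻¹` is exactly `[1,0,0]`, so
the z-component inherits the reference channel unamplified.

Detector noise is additive circular complex Gaussian with per-component
std σₙ, assumed equal across acquisitions (same scanner, same
processing). Amplitudes are then Rice distributed: below SNR 3 the
amplitude estimate is biased upward (computed deterministically from
the Rice mean via `scipy.stats.rice`, not by sampling), which motivates
the floors `A_min = 3σₙ` and `A_min⁽ᵈ⁾ = 3·NAF_max·σₙ`. Above SNR 3
the phase std is `σₙ/A_t`; at exactly SNR 3 this is 1/3 rad while the
mean absolute phase error is `√(2/π)/3 ≈ 0.27` rad — both statistics
are reported because published "phase error" figures rarely state which
one they are.

Axis-estimation error is modelled as a cone of semi-vertical angle ε_r
around each true axis; erroneous axes are sampled on the cone boundary
uniformly in azimuth (seeded, or on a regular grid). The decomposition
error `ε_d = v_true − v_est` is linear in the stimulus amplitude, so
doubling the amplitude raises the amplitude error by exactly
20·log₁₀2 = 6.02 dB. The "amplitude component" of ε_d is reported as
`|v_true| − |v_est|` and the "phase component" as the wrapped angle
difference; the sign conventions are package choices.

## Optical-axis estimation by surface registration

Surfaces are extracted from C-scans as the first voxel at or above the
reflectivity threshold (50 dB by default, boundary inclusive for
deterministic masks) along each transverse column — appropriate for
opaque, non-penetrating objects and deterministic. Registration of a
moving to a fixed cloud proceeds in three stages:

1. **Hypothesis generation.** (a) RANSAC over correspondences between
   salient points (high neighbourhood normal spread / covariance
   scatter), matched by rotation-invariant eigenvalue descriptors, with
   pairwise-distance consistency and oriented-normal checks; seeded.
   (b) A heightfield scan: the dominant oriented surface normals of the
   two clouds are aligned, the remaining rotation about that normal is
   scanned on a 7.5° grid, and each candidate's translation is solved by
   masked correlation of rasterized top-surface height images. The scan
   complements RANSAC because local descriptors carry almost no
   information on piecewise-flat geometry. Normals are *oriented* (facing
   the beam, −z in each cloud's own frame), which rejects flipped
   plane-on-plane alignments that unsigned normals cannot distinguish.
2. **Selection.** All hypotheses are ranked by a symmetric coverage
   score (inlier fractions in both directions, with oriented-normal
   agreement); the best few receive a short ICP refinement and the best
   basin wins.
3. **Refinement.** Point-to-plane ICP with two outlier guards — a
   distance gate that shrinks toward the residual level and rejection of
   normal-incompatible pairs (surface patches visible from only one
   view, e.g. stair risers seen obliquely, otherwise bias the rotation).
   Because near-planar scenes leave in-plane motion unconstrained by
   point-to-plane residuals, crease/edge points detected in both clouds
   add point-to-point residuals to the same linear system. A final
   point-to-point Kabsch polish is accepted only when it clearly lowers
   the residual; for identical point sets it converges to machine
   precision.

The estimated optical axis is the third column of the recovered 4×4
transform. Registration quality is measured as the acute angle between
least-squares planes fitted to a designated flat region (an axis-aligned
box in the reference frame, by default the phantom's highest step) of
the fixed and the transformed moving cloud. This plane-angle metric is
invariant to in-plane rotations; note it has a nonzero floor
(~0.1–0.3° at 25 µm voxels with 10 µm jitter) from first-crossing
voxelization alone, i.e. even a perfect transform does not score zero.

## Assembly, fusion and mesh mapping

Cross-sections are placed in the C-scan by normalized cross-correlation
of in-plane gradient-magnitude images over integer-voxel shifts
(±3 voxels around the calibration pre-alignment) with parabolic
sub-voxel refinement; refinement is skipped at near-perfect correlation
where the integer peak is already exact, and ties (featureless
directions) resolve toward the pre-alignment. All scattered-to-grid
steps use nearest-neighbour interpolation with *no extrapolation* and a
support radius of 1.5× the maximum voxel pitch (configurable; the
radius is a package choice). Nearest-neighbour ties resolve to the
smallest data index, so resampling is deterministic and never invents
values.

Voxel-level fusion inverse-transforms reference voxel centres into each
moving grid; voxels holding the reference value plus at least two other
measurements are decomposed with the axes of the first two contributors
(in configuration order); fewer than three contributions leaves the
voxel undecomposed, and locally singular axis triplets are skipped and
counted. Mapping to a surface mesh drops data outside the mesh
neighbourhood and below `A_min⁽ᵈ⁾` (using the overall amplitude
`√Σ|vᵢ|²`), assigns vertices within 0.1 mm of a surviving datapoint by
nearest neighbour, and fills the remainder by multi-source Dijkstra
over the mesh edge graph (each unassigned vertex inherits the value of
the nearest assigned vertex along the mesh).

## The synthetic phantom

The generator emulates a rigid, opaque, stair-featured object on a
shaker: an analytic heightfield with four asymmetric steps along x
(heights 0.2/0.45/0.8/0.6 mm, widths 0.9/0.7/1.1/0.5 mm) and a smaller
asymmetric cross stair along y (heights 0/0.3/0.15 mm) that breaks the
extrusion symmetry — without it a surface registration cannot constrain
translation along the step direction. Default voxel pitch is 25 µm;
reflectivity is 80 dB at the surface decaying 40 dB/mm with depth over
a 20 dB background. These dimensions are declared fixture parameters of
the synthetic object, not measured properties of any physical phantom.
Rotated views are rendered by sampling the analytic geometry on a grid
rotated into the measurement frame, so registration studies have exact
ground-truth transforms and no image-resampling error.

Motion is either uniform (one complex velocity vector everywhere — the
rigid-phantom assumption) or a hinged rigid rotation
`v(p) = Ω×(p−p₀)`, whose axial projection grows linearly with the
moment arm and flips phase by π across the hinge — the qualitative
low-frequency signature of ossicular motion, testable synthetically.

Noise is injected at the reconstructed-tone level with per-component
std σₙ; the equivalent raw-snapshot mode adds real noise of std
`σₙ√(N/2)` to the instantaneous velocities, which the correlation
filter (per-component variance gain 2/N) maps to the same tone
statistics. For threshold studies an optional reflectivity-dependent
mode scales the local noise std by `10^((R_ref−R_dB)/20)`, emulating
the loss of sensitivity at low sample reflectivity; decomposition
studies use constant σₙ (the equal-noise assumption of the model).

What the phantom does *not* emulate: speckle, shadow casting,
depth-of-focus and refractive bending (the PMMA refractive index is
carried as metadata only), ear-canal acoustics, or sub-surface
refractive correction. Passing tests therefore demonstrate the
correctness of the reconstruction/registration/decomposition chain and
its noise theory under the stated noise model, not robustness to those
optical effects.

## Problem sizes and numerical choices

Validation studies run at the phantom's native 25 µm pitch
(~135×135×55 reference voxels, ~16 k surface points per cloud); unit
tests use a 50 µm pitch for speed. The registration-accuracy study uses
ten seeded trials cycling the six rotated-view orientations with polar
angles 10–40°; side-on views (θ = 90°) are excluded because a
first-crossing cloud seen from the side shares essentially no surface
with the top-view reference, making the registration ill-posed for this
geometry. Monte-Carlo noise checks use 10⁵ draws (2% tolerance on
stds), distribution checks 10⁴ draws. Angles are degrees at all public
interfaces and radians internally; coordinates are right-handed, in mm,
with voxel-centre convention and 0-based indices; anatomical-frame sign
conventions (medial/superior) are supplied by the caller as hint
vectors since they are anatomical, not numerical, facts.

## Known limitations

- Only exactly three measurements decompose a voxel; no N>3
  least-squares fusion.
- Sub-surface voxels are positioned without refractive correction.
- The gradient-correlation slice alignment localizes only along
  directions in which the scene has gradient content; featureless
  directions stay at the pre-alignment.
- High-amplitude timing-jitter noise is not modelled.
- The plane-angle registration metric includes a voxelization floor and
  is blind to rotation about the fitted plane's normal; axis-direction
  error is reported alongside it in the registration report.
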