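# octvib

Serial single-beam 3D optical-coherence-tomography (OCT) vibrometry:
reconstruct per-pixel complex vibration tones from stimulus-synchronous
phase data, estimate the optical axis of each acquisition by surface
point-cloud registration, and decompose multi-direction axial velocity
measurements into Cartesian 3D vibration vectors — together with the
noise theory needed to judge how trustworthy the decomposition is.

The package targets researchers in middle-ear mechanics (and anyone
doing multi-angle Doppler OCT) who measure nanometre-scale vibrations of
structures such as the malleus–incus complex with a single-beam scanner
that is re-oriented between acquisitions, rather than with a fixed
multi-beam optical bench.

## The method

A phase-sensitive OCT system measures, at every pixel, only the
projection of the local velocity onto the beam axis. For measurement
*n* with unit optical axis **d**ₙ:

```
vₙ = v · dₙ ,   vₙ ∈ ℂ
```

Stacking three acquisitions with linearly independent axes (the
reference axis defines the world frame, so **d**₁ = [0,0,1]ᵀ) gives the
*orthogonal decomposition*

```
v = O⁻¹ m ,   O = [d₁; d₂; d₃] ,   m = (v₁, v₂, v₃)ᵀ
```

with `det O = sinθ₁ sinθ₂ sin(φ₂−φ₁)` in spherical axis coordinates —
singular when either non-reference axis approaches the reference axis or
both share an azimuth.

Because the inversion is linear it amplifies the additive circular
complex Gaussian detector noise: the decomposed x/y noise standard
deviations are `NAF_x,y · σₙ` where the *noise amplification factor*
NAF is the Euclidean norm of the corresponding row of `O⁻¹`. Amplitudes
of complex Gaussian signals are Rice distributed, biased upward below a
signal-to-noise ratio of 3, which sets the noise floors

```
A_min = 3 σₙ ,   A_min⁽ᵈ⁾ = 3 · NAF_max · σₙ
```

and the high-SNR phase error `σ_φ = σₙ / A_t`.

The axes themselves are estimated by registering first-crossing surface
point clouds of the C-scans (coarse hypothesis search + point-to-plane
ICP); the registration error is quantified as the angle between
least-squares planes fitted to a designated flat surface of the fixed
and transformed clouds.

Every stage is validated end-to-end on a synthetic rigid stair-featured
phantom with analytic geometry and exactly known motion, axes and noise.

## Worked example

```python
import numpy as np
from octvib import (AcquisitionSchedule, MotionSpec, PhantomSpec,
                    simulate_dm, fuse_dms, build_direction_matrix,
                    propagate_noise, amplified_noise_floor)

spec, sched = PhantomSpec(spacing=0.05), AcquisitionSchedule()
v_true = (0.3 + 0.1j, 0.2 - 0.05j, 0.4 + 0.2j)   # mm/s, complex tone
motion = MotionSpec(velocity=v_true)

ref = simulate_dm(spec, motion, sched, sigma_n=0.0, seed=0, name="Z")
a = simulate_dm(spec, motion, sched, 0.0, seed=1, theta_deg=40, phi_deg=0)
b = simulate_dm(spec, motion, sched, 0.0, seed=2, theta_deg=30, phi_deg=30)

fused = fuse_dms(ref, [(a, a.truth["transform"], a.truth["axis"]),
                       (b, b.truth["transform"], b.truth["axis"])])
pts, vals = fused.points_and_values()
print(len(vals), vals.mean(axis=0).round(6))

O = build_direction_matrix(a.truth["axis"], b.truth["axis"])
print(round(O.naf_x, 3), round(O.naf_y, 3),
      round(amplified_noise_floor(0.033, O=O), 3))
```

prints

```
55641 [0.3+0.1j  0.2-0.05j 0.4+0.2j ]
1.96 5.022 0.497
```

— the fused decomposition recovers the simulated motion vector exactly
at every one of the 55 641 mutually visible voxels (noiseless case), and
for this axis geometry (NAF_max ≈ 5.0) detector noise of 0.033 mm/s per
component would make vibration amplitudes below 0.497 mm/s unreliable in
the decomposed x/y components.

The same chain is available from the shell:

```
octvib all --config config.json --seed 0 --out results/
```

which writes per-view C-scans, the registration report (estimated axes,
plane-angle errors), the decomposition report (NAFs, |det O|, σ̂ₙ,
noise floors) and the fused Cartesian field.

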