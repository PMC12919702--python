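# Methods

This note records the models implemented in `fovxtend`, the conventions
and numerical choices behind them, and what the synthetic tests do and
do not establish about real data.

## Offset-COR geometry

The scanner is a straight source–mask–object–detector line with the
rotation axis displaced by `delta_cor` perpendicular to it. All
quantities live in SI units (meters, radians); configs may use unit
suffixes (`mm`, `um`, `deg`, `s`).

Conventions (fixed once, used everywhere):

* COR at the origin; the source–detector pair rotates counter-clockwise
  about it. At `α = 0` the source sits at `(delta_cor, −z_so)` with
  `z_so = z_sm + z_mo`, the detector center at `(delta_cor, z_od)`, and
  the column axis along `+x`. Detector coordinate `x` is the signed
  distance from the detector center; pixel `i` is centered at
  `(i − (n_col−1)/2)·p`.
* `τ` is the signed angle between the central ray and the COR ray,
  `τ = −atan(delta_cor/z_so)`. The sign is forced by the convention
  that positive `delta_cor` puts the singly-covered (FOV-extension)
  region on the `+x` half of the detector: the conjugate-ray relation
  `γ' = 2τ − γ` then places the doubly-covered interval
  `[−p·n_col/2, R·tan(γ_max − 2|τ|)]` on the `−x` side, and the weight
  ramps 0 → 2 left to right. Negative `delta_cor` mirrors everything.
* Field of view: the first-order sample-plane convention
  `fov_extended = p·n_col/M + 2|delta_cor|` reproduces the headline
  numbers of offset scans at small fan angles; the exact radii of the
  always-seen circle C1, `r1 = z_so'·sin(γ_max − |τ|)`, and of the
  ever-seen circle C2, `r2 = z_so'·sin(γ_max + |τ|)`
  (`z_so' = √(z_so² + delta_cor²)`), are derived alongside.
* A redundant region exists only for `|τ| ≤ γ_max`, i.e.
  `|delta_cor| ≤ fov_native/2` (extension factor ≤ 2).

## Redundancy weighting

Inside the redundant interval,

    W(x) = 1 − sgn(τ)·sin( (π/2)·(atan(x/R) − τ) / (γ_max − |τ|) ),

clamped to the 0/2 branches outside. Four properties pin this form
regardless of algebraic presentation: `W = 0` at the detector edge on
the redundant side, `W = 2` at the inner boundary of the singly-covered
region, `W = 1` on the COR ray `x_c = R·tan τ`, and `W(γ) + W(2τ−γ) = 2`
for every conjugate pair. The suite asserts all four to 1e-9 over 50
random geometries. At `τ = 0` the weight is identically 1 and the
pipeline reduces to ordinary full-scan FBP (asserted voxelwise).

## Reconstruction pipeline

Order of stages: divergent-beam cosine pre-weight `R/√(R²+x²)` →
padding → row-wise Ram-Lak filtering → un-padding → redundancy
weighting → backprojection. Weighting after the filter preserves the
smoothness of the filtered rows across the redundancy transition; the
test suite pins the composition (weight-after-filter, not the
reverse).

**Padding.** The truncated side receives a reversed copy of the
measured row, the other side constant edge values, then the row grows
to an FFT-friendly length. The reversed copy is aligned on the COR-ray
column, not the detector edge: since conjugate rays satisfy
`γ' = 2τ − γ`, the value at a cut-off coordinate `x` is estimated by
sampling the row at `R·tan(2τ − atan(x/R))`. This makes the padding a
genuine estimate of the missing rays (exact for objects symmetric about
the COR, accurate to the fan angle otherwise). The distinction matters
quantitatively: with the reversed copy aligned on the detector edge
instead, the truncated-disk benchmark reconstructs ~19% low; with
conjugate alignment the error is 0.01% and the residual discontinuity
at the C1 boundary stays within twice the interior noise. The generic
edge-aligned `pad_for_filtering` remains available and is used when
`τ = 0`.

**Ramp filter.** Pure band-limited Ram-Lak, built as the DFT of the
discrete kernel `h[0] = 1/(4Δx²)`, `h[k] = −1/(πkΔx)²` for odd lags,
zero at even lags (no apodization). The kernel's small DC response
(`4/(π²N)` for an N-sample circular buffer) is retained deliberately:
zeroing the DC bin biases homogeneous-object reconstructions by ~3%.
Consequently a constant row filters to ~1e-3 of its value at typical
padded lengths rather than to machine zero, improving as 1/N.

**Backprojection.** Vector geometry: each voxel is projected from the
per-view source position onto a virtual detector plane through the COR,
sampled with linear interpolation between columns (nearest detector
row, half-pixel ties toward the lower index), and accumulated with the
distance weight `(U₀/U)²`, where `U₀` is the source-to-COR distance
along the central-ray direction and `U` the same projection of the
voxel; the sum is scaled by `π/n_angles`. `U₀` equals the axial
distance `z_so` for these geometries; the full source–COR distance
`z_so'` differs from it by a factor `1 + tan²τ` (≈ 4e-5 here), so the
choice is numerically irrelevant but `U₀` is the exact displaced-
detector fan-beam constant. 3-D stacks are handled as row-independent
fan reconstructions (FDK-style approximation); the tests use the
central row.

## Beam-tracking retrieval

Each beamlet is modeled as a Gaussian plus constant background, fit by
least squares per window of ± half a period (up to 200 iterations;
non-convergent or amplitude-below-noise fits are flagged and propagate
as masked entries). Channels per beamlet pair (sample vs flat):

* transmission `t = (A_s σ_s)/(A_f σ_f)` — the area ratio;
* refraction `θ = (c_s − c_f)/z_od`, positive `θ` displacing the
  beamlet toward `+x`; `θ = ∂x ∫δ dz` (paraxial, monochromatic);
* dark-field `(σ_s² − σ_f²)/z_od²`, clamped at zero — angular variance
  is additive along the path, which is what makes it a line integral
  (asserted by the stacked-scatterer test).

The exact shape model used by any particular instrument's retrieval may
differ (e.g. moment-based tracking); the invariants checked here —
identity on flat frames, channel arithmetic, additivity, end-to-end
round trip — are model-agnostic, but the dark-field normalization may
differ from other conventions by a constant factor (the convention is
recorded in output sidecars).

Dithering: successive steps translate the sample so that the beamlet
comb advances by `period/n_dither` across it; interleaving the
per-beamlet samples in step order (`[a0, b0, a1, b1, …]`) yields maps
at the effective sample-plane pitch `period_sample/n_dither` (84 µm / 8
= 10.5 µm for the large-FOV configuration). Interlacing is a pure
permutation of the measured samples.

Phase integration: `∫δ dz` is obtained by cumulative trapezoidal
integration of `θ(x)` anchored at zero in the outermost three effective
pixels of the non-truncated side (configurable); a margin whose mean
exceeds 5× the noise scale triggers a warning but integration proceeds.
Because the offset geometry always leaves one sample-free side, the
boundary constant is known exactly — this is what makes the phase
channel quantitative despite one-sided truncation.

## Paganin retrieval

`T = −(1/µ)·ln F⁻¹[ F(I/I₀) / (1 + (δ/β)·z_eff·λ·|k|²/(4π)) ]` with
`µ = 4πβ/λ`. The ratio `δ/β` defaults to 25 (under-retrieval preferred
for resolution on soft tissue); the wavelength defaults to the 8 keV
line (λ = 1.55 Å). On a cone-beam system the Fresnel scaling theorem
gives `z_eff = z_od/M` and effective pixel `p/M`; both are recorded in
output sidecars since raw-versus-magnification-corrected conventions
differ between tools. Images are mirror-padded by half their size
before the FFT. `µT` is always returned; metric thickness and phase
require `δ` explicitly.

## Virtual scanner

Phantoms are unions of constant-density disks/ellipses with three
densities: attenuation `µ` (1/m), phase decrement `δ` (dimensionless;
`∫δ dz` in meters), and angular-variance density (rad²/m). Line
integrals are exact chord lengths (quadratic formula in the primitive's
unit-circle frame), validated against dense numerical ray integration.
The refraction ground truth is the central finite difference of the
phase sinogram at the COR-plane column pitch, matching the definition
used by the retrieval; beamlet physics (attenuation, shift, broadening)
is applied per beamlet at the beamlet center with no intra-beamlet
gradient — valid for phantoms that vary slowly over one mask period and
a documented limitation near sharp edges. Fresnel propagation uses the
angular spectrum (energy-conserving; warns beyond the aliasing-free
distance `N·Δx²/λ`). Poisson noise is applied last from a single seeded
generator; seeds are recorded in sidecars.

What the synthetic tests do **not** cover: detector point-spread-
function bias (a known artefact source in the real system's retrieval),
polychromatic spectra, partial-coherence source blur, scattering beyond
Gaussian angular broadening, and mechanical instabilities. Passing the
suite therefore demonstrates correctness of the geometry, weighting,
filtering and retrieval algebra — not robustness to these instrument
effects.

## Problem sizes and tolerances

Default test scale: 256 detector columns, 720 views, 256² voxel grids
for the reconstruction benchmarks (a few seconds each); 200 Monte-Carlo
repeats at 10⁴ counts/beamlet for retrieval noise (seeded,
deterministic). Key asserted tolerances: weight identities 1e-9;
offset-vs-conventional RMSE inside C1 ≤ 3% of contrast (measured
~0.003%); interior densities within 5% (measured 0.01–1.2% across
channels and an off-center ellipse); noiseless retrieval within 1%
(measured ~1e-5); Paganin thickness within 5% (measured 0.01%);
truncation discontinuity at the C1 boundary ≤ 2× interior noise,
measured on the residual against the non-offset reference so the shared
disk-edge gradient does not mask the truncation-specific artefact.
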