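# Methods

## Forward model

Magnetic fields are computed with the closed-form solution for a current
dipole in a homogeneous, spherically symmetric conductor (the Sarvas
formula). The field depends only on the dipole position relative to the
sphere centre, not on the sphere radius or conductivity, and radial
dipoles are exactly silent — the package therefore represents every
source by two tangential components. The geometry lives in a
right-handed head frame in metres with the conducting sphere centred at
the origin.

Sensors are treated as point integrators. A magnetometer reads the
field projected on its coil normal; a planar gradiometer reads
`(B(p + d/2·a) − B(p − d/2·a))·n̂ / d`, a two-point finite difference of
the radial-projected field along the tangential differencing axis `a`
at the physical baseline `d = 16.8 mm`. This mirrors how planar
gradiometer coils are wound, keeps a single field kernel, and converges
to the analytic directional derivative as `d → 0` (verified by
Richardson extrapolation in the tests). No coil-area integration is
performed; at 50–120 mm source-to-sensor distances the point
approximation is standard.

Correctness of the field kernel is cross-checked against two
independent oracles: the numerical gradient of the magnetic scalar
potential `B = −μ₀∇U`, and the identity that the radial field component
outside a spherical conductor equals the Biot–Savart term of the dipole
element alone.

## Montage operator

Given a lead field `L`, per-channel noise SDs `σ_i` and a
regularization fraction λ:

1. whiten: `W_b = diag(1/σ_i)` (a full-covariance inverse square root is
   also supported),
2. depth-weight: `W_s = diag(column norms of W_b L)`, so
   `L_n = W_b L W_s⁻¹` has a unit-diagonal Gram matrix `L_nᵀL_n`,
3. invert: `transform = W_s⁻¹ (L_nᵀL_n + λI)⁻¹ L_nᵀ W_b`.

The de-normalization by `W_s⁻¹` means applied waveforms are physical
source amplitudes in A·m. Because the Gram diagonal is 1, λ is a
percentage of per-component signal power; λ = 0 is allowed (a warning
fires when the Gram condition number exceeds 1e12) and the solve uses a
symmetric positive-definite Cholesky factorization with a symmetric
fallback. With λ = 0, full column rank and P ≤ M the operator is an
exact pseudoinverse (tested to 1e-10 relative error).

Display modes: 58 raw components; 29 RMS traces
(`sqrt(mean of squared components)` per location); or 29
principal-orientation traces. The principal orientation is the leading
eigenvector of the 2×2 matrix `S Sᵀ` of the windowed component block,
re-estimated per analysis window; the projection is applied to the full
trace. Ties (eigenvalue ratio < 1 + 1e-9, i.e. a rotating source) fall
back deterministically to the eigenvector with the larger e_θ weight,
and the sign is fixed so the windowed peak is positive. An all-zero
window yields a flagged undefined orientation and a zero trace.

Note a known property, not a defect: the regularized (λ > 0) inverse
introduces deterministic cross-talk between the two components of a
location, which can rotate the recovered principal orientation by up to
~8° at λ = 2% on this geometry even without noise. Orientation-accuracy
tests therefore gate on the unregularized chain or on pure component
fixtures, where the ≤ 5° behaviour at ≥ 30 dB holds.

## Synthetic study geometry

No proprietary device geometry or subject anatomy ships with the
package; all geometry is generated:

- **Helmet** — 102 sites on a Fibonacci lattice over a spherical cap of
  half-angle 2.2 rad at radius 120 mm, three channels per site (radial
  magnetometer + two orthogonal planar gradiometers). Default noise SDs
  are 200 fT (magnetometers) and 50 fT/cm = 5e-12 T/m (gradiometers),
  the usual figures for unaveraged epochs. The construction is a stand-in
  for a commercial 306-channel layout, not a copy of one.
- **Regional sources** — 29 labelled locations (5 midline + 12
  left/right pairs, labels such as FC6R, TPL, FpM) on a 70-mm shell
  covering frontal, central, temporal, parietal and occipital cortex.
  The clinical montage's true coordinates are not public; this layout is
  a documented synthetic stand-in and can be replaced by any JSON file
  with the same schema.
- **Tangential bases** — spherical-coordinate unit vectors (e_θ, e_φ)
  about the +z pole; on the polar axis the pair degenerates and (x̂, ŷ)
  is used. Any fixed orthonormal tangential pair is equivalent for the
  montage.
- **Cortical grids** — per hemisphere, a recursively subdivided
  octahedron projected to a sphere (4^(levels+1) + 2 vertices; 4098 at
  level 5) of radius 45 mm centred at (±22, 0, 10) mm. The lateral
  offset makes surface normals oblique — up to ~30° from the head-model
  radial direction — so normal-oriented patch sources are neither silent
  nor fully tangential, and vertex depths below the helmet span a
  realistic 50–100 mm. A concentric sphere (tiny offset) was rejected:
  its normals would be nearly radial and nearly every patch source would
  be magnetically silent. A smooth sphere cannot reproduce both the
  folded cortical surface area and head-scale radii, so 1-ring patch
  areas match the cortical ~1 cm² figure near subdivision level 4 and
  shrink at level 5.

## Simulation conditions

The study conditions are: 4 cycles of a 20-Hz sinusoid (200 ms) once
per second, peak amplitude 100 nAm, placed in the last 200 ms of each
1-s epoch so the preceding 800 ms is the baseline; 10 s of data at
1000 Hz (sampling rate chosen as a typical MEG rate, giving 200-sample
bursts); background of independent Gaussian noise per channel at the
nominal channel SD; the sum band-pass filtered to 2–70 Hz with a
zero-phase (forward–backward) 4th-order Butterworth filter. Burst phase
starts at zero at the window onset. Three scenario families exist:
dipoles along (e_θ+e_φ)/√2 at the 29 montage locations; 25 procedurally
scattered tangential dipoles per hemisphere at radii 35–70 mm (the
historical 50-dipole set's coordinates are not public); and one patch
source per grid vertex (seed + 1-ring neighbours, dipoles along local
normals, total moment 100 nAm split equally — the split keeps patch
strength comparable to the point-dipole scenarios). All randomness
derives from a single spec seed through a spawned seed sequence, making
every scenario a pure function of (spec, seed).

The synthetic background is band-limited white noise: it reproduces
channel noise levels but none of the spatial correlation, 1/f spectrum
or alpha rhythms of real resting-state activity. Passing tests
therefore demonstrate operator correctness and relative trends, not
clinical SNR values; a real recording can be substituted via the FIF
ingestion hook.

## SNR and readouts

Per channel and epoch, `SNR = 20·log10(P_s/P_b)` where `P_s`, `P_b` are
mean squared deviations from the baseline mean over the signal and
baseline windows; values are averaged over the 10 epochs. The
prefactor 20 on a power ratio is deliberate — it is the printed
convention for this montage-evaluation statistic, and all quoted dB
values (including the 15-dB detectability threshold) follow it; under
the usual 10·log10 convention every number would be halved. Epochs with
zero baseline power return a +inf sentinel and are excluded from the
average with a warning, so noiseless limits remain expressible.
Epoch segmentation starts at t = 0; partial trailing epochs are
dropped. `Ndt` counts channels with SNR ≥ threshold (inclusive);
sensor-level and montage-level counts use the same 15-dB threshold.

The amplitude readout at the best-SNR montage channel is, by default,
the sinusoid-equivalent amplitude `√2 × RMS` over each epoch's signal
window, averaged over epochs. For a burst filling the window this
equals the sinusoidal peak, and it is robust to the two biases that
affect a raw per-sample peak: band-pass ringing (the zero-phase 2–70 Hz
filter overshoots the burst peak by ~5%) and baseline noise (which
inflates a windowed maximum by up to ~25% through the unregularized
306-channel inverse at default noise). `peak` (per-epoch maximum,
averaged) and `average_peak` (maximum of the time-locked epoch average)
remain available as documented alternatives.

## Numerical and scale choices

- Singular geometries raise: field points at the dipole, vanishing
  Sarvas factor F, sources at the sphere centre, magnetically silent
  lead-field columns (reported by component name).
- The regularization sweep covers λ ∈ {0, 0.5, 1, 2, 3, 4, 5}% × the
  three channel subsets, matching the montage-location scenario.
- Test and example problem sizes are scaled for a desk run: the
  systematic cortical seeding uses level-3 grids (258 patches per
  hemisphere) in the test suite and level 2 in the example; the full
  level-5 study (4098 per hemisphere) runs with the same code path by
  raising `grid_levels`.

## Known limitations

- Spherical conductor only; no BEM/FEM, no EEG potentials.
- The 29-location layout and the scattered-dipole sets are synthetic
  stand-ins, so absolute SNR tables are not comparable to
  device-specific published values; monotone trends in λ, depth and
  channel subset are.
- Homogeneous-noise background (see above); no environmental
  interference model, no coil-geometry integration.
- Only a scalar λI regularizer is exercised; the general diagonal
  regularization matrix and full source-covariance solution are out of
  scope (the full noise covariance *is* supported in the whitener).
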