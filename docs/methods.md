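# Methods

This note documents the models and estimators implemented in `umi`, the
numerical choices behind them, the synthetic study conditions, and the
known limitations.  Units are mm / µs / MHz throughout (sound speed in
mm/µs); screen delay spreads are quoted in ns.

## Acquisition model

The generator (`umi.simulate`) produces complex-baseband (IQ) channel
data under the single-scattering (Born) approximation.  Each trace is

```
R(i_in, u_out, t) = Σ_s γ_s T(u_in) T(u_out) g_in g_out
                    · env(t − τ_in − τ_out) · exp(−2iπ f_c (τ_in + τ_out))
```

with `γ_s` circular-Gaussian reflectivities, `g = z/(4π d²)` the
obliquity-weighted spherical spreading inside a hard directivity cone
(half-angle θ_max, matching the beamformer's aperture rule, so forward
and inverse models stay consistent), and `env` a Gaussian envelope whose
−6 dB spectral width equals the probe's fractional bandwidth (default
80% of 3 MHz; a band-equivalent stand-in for a short tone burst).  IQ
demodulation is at f_c with baseband sampling f_s = 2 f_c = 6 MHz.

Three properties are exact by construction and are tested as such:
transducer-basis reciprocity (`R(i,j,t) == R(j,i,t)` bit for bit — the
pairwise factor is computed as `γ·(c_i·c_j)`, which commutes exactly in
IEEE arithmetic), Born linearity over scatterer sets, and losslessness of
the unit-modulus phase screen.

**Phase screen.** The aberrator is a thin screen at the probe plane:
white Gaussian noise per element smoothed with a Gaussian kernel of width
`correlation_length / 2` (the screen autocorrelation then falls to 1/e at
one correlation length), de-meaned and rescaled so that
`rms(φ) = 2π f_c τ_rms` exactly.  The screen multiplies both legs of
every echo and is angle-independent — the thin-screen premise that the
correction framework assumes.

**Nuisance components.** The multiple-scattering surrogate is a
time-resolved complex Gaussian random matrix symmetrized over the element
pair, band-limited by the pulse and decaying exponentially from the first
scatterer arrival.  Electronic noise is iid complex Gaussian.  The
surrogate reproduces the *symmetry structure* that the β estimator
exploits (reciprocal vs non-reciprocal energy), not multiple-scattering
physics; it is defined in the transducer basis only.

**Speckle density.** `sample_speckle_medium` counts scatterers per
(λ_c/2)³ cell (Poisson-distributed total).  Because reflectivities are
circular Gaussian, every linear functional of the medium is circular
Gaussian, so fully developed speckle statistics hold at any density;
fixtures use low densities (~0.05–0.13 per cell) to keep the Born sums
fast, at the cost of sub-resolution sampling granularity only.

**Plane-wave transmits** are the coherent per-element sum evaluated at
f_c with the envelope pinned at the geometric plane-wave arrival
(narrowband thin-screen approximation for the transmit leg).

## Beamforming

`beamform_focused_matrix` evaluates the delay-and-sum definition

```
R(ρ_in, ρ_out, z) = Σ_i Σ_j A_in(i, r_in) A_out(j, r_out)
                    · R(i, j, τ_in + τ_out) · exp(+2iπ f_dem (τ_in+τ_out))
```

with times of flight `τ(u, r) = |u − r|/c₀` (transducer) or
`τ(θ, r) = (x sinθ_x + y sinθ_y + z√(1−sin²θ_x−sin²θ_y))/c₀`
(plane wave), and a binary cone apodization (element kept when the focal
point lies inside its directivity cone; no taper — a taper hook exists
but the default matches the simulator's hard cone).

*Interpolation and factorization.*  Trace values at off-sample delays use
band-limited (discrete-Fourier) interpolation on a per-depth time window.
This is the natural interpolant for band-limited IQ data and makes the
sum exactly separable per frequency,

```
R_z = (1/n_w) Σ_m E_in[m]^T X[m] E_out[m],
```

so the production path is three matrix products per frequency and depth —
and agrees with the brute-force nested-loop reference (`reference_das`)
to machine precision, because both evaluate the identical finite sum.
Two-stage linear interpolation, the usual fast alternative, is *not*
exactly equivalent to its own naive reference (O(dt²) discrepancies), and
one-stage linear interpolation does not factorize.

Aberration-corrected (adaptive) focusing falls out of the same
factorization: a per-voxel unit-modulus law `T(channel, voxel)` to be
compensated enters `E_in`/`E_out` as a frequency-independent conjugate
weight, at no extra cost and with no approximation.

Storage: per-depth dense complex matrices with entries beyond
`|Δρ| > Δρ_max` zeroed and masked (default Δρ_max = 10 mm; default voxel
pitch 0.5 mm ≈ λ).  The de-scanned (common-midpoint) view is a pure
relabelling `R_M(Δρ, r_m) = R(r_m − Δρ/2, r_m + Δρ/2)`, stored anchored
at the input point with NaN where no grid partner exists.

## RPSF and scattering rates

The local RPSF averages `|R_M(Δρ, r_m)|²` over midpoints inside box
windows (w_ρ, w_z); windows with fewer than 10 midpoints are flagged.
Resolution is the equivalent −3 dB radius `δρ = √(A/π)` with A the
half-maximum area of the *amplitude* profile, restricted to the connected
region around the peak (an unconnected bright background must not count);
plateau-dominated profiles are flagged.  The background level α_B is the
median normalized intensity over the de-scanned annulus
`6 δρ₀(z) < Δρ ≤ Δρ_max` — the median resists residual peak leakage —
and the contrast is `F = (1 − α_B)/α_B` (capped and flagged when
degenerate).  β is the energy fraction of `(R − R^T)/2` on the same
de-scanned support; `α_M = (1 − 2β) α_B`, `α_N = 2β α_B`, with β > 1/2
treated as a sampling fluctuation (α_M clipped at 0).

At shallow depth the directivity cone makes the noise plateau spatially
non-uniform (edge anchors see fewer elements); scattering-rate studies
therefore beamform with the full aperture (`apodization="none"`).

**Calibrated mixtures.** Raw-domain component weights have no canonical
scale, so `calibrated_mixture` defines injected rates on the quantity the
decomposition actually measures: the normalized-RPSF background
fractions.  It beamforms the three components separately, measures each
component's confocal and plateau levels, and solves a 2×2 system for the
component scales.  The reciprocal surrogate exhibits a coherent confocal
doubling (a symmetric random matrix has twice the variance on its
monostatic diagonal) which the calibration must budget — without it a
50% background fraction is unreachable.  Recovery from the mixture
(β split plus median-based α_B) remains a genuine estimation problem.

## Aberration estimation and correction

Projection to the correction basis uses, per depth, the z-derivative
Green's amplitude `z·e^{−ik_c d}/(4π d²)` (transducer basis) or the
unit-modulus Fourier kernel `e^{i k·ρ}` on the grid-matched k comb
(Fourier basis; modes outside the directivity aperture are marked
inactive and carry flat laws).  The propagation phase is conjugated with
respect to the outgoing wave so that `R × G` undoes the beamformer's
receive-focusing rotation; with the opposite sign the projection
scrambles the wavefront (verified numerically on a guide star).

`D = G* ∘ (R × G)` then isolates the aberration: near a bright target,
`arg D(u)` reproduces the screen phase.  Patch correlation matrices
`C(c, c′, r_p) = ⟨D(r, c) D*(r, c′)⟩_{r ∈ W}` feed the iterative phase
reversal fixed point `T̂ ← exp[i arg(C T̂)]` (flat-phase start, tolerance
1e−3 rad on the largest per-channel update, 100 iterations maximum,
global phase pinned on the first active channel).  On rank-1 matrices IPR
equals the leading-eigenvector phase; an eigendecomposition serves as an
independent oracle in the tests, never as the estimator.

*Sub-band estimation.*  A broadband focused matrix projected at the
centre wavenumber alone carries a chromatic bias: each spectral component
maps the screen to a radially stretched coordinate, blurring the
estimate (guide-star law fidelity saturates near 0.85 circular
correlation).  The estimator therefore beamforms 4–6 narrow slices of
the pulse band — nearly free, since the factorized DAS cost is
proportional to the number of frequency bins — pairs each with a
propagator at its own centre wavenumber, and sums the patch correlation
matrices over slices (for a thin *phase* screen the law is
frequency-independent, so the sub-band estimates are coherent).  This
raises guide-star fidelity to ≥ 0.96 and converged speckle recovery to
≈ 0.98.

*Correction routes.*  In the Fourier basis the focal-domain update
`R ← [(R × G) ∘ T̂†] × G†/N` is exact (unitary transform; a flat law is
the identity to machine precision, and successive corrections compose).
In the transducer basis the same update needs a pseudo-inverse whose
truncation amplifies out-of-range residuals on a finite field of view;
it is provided (rcond 1e−2) but the multi-scale driver prefers the exact
route whenever the raw transducer-basis acquisition is available:
stitched per-voxel element laws are compensated directly in the
beamformer (adaptive focusing), with laws accumulating multiplicatively
across steps and the matrix rebuilt from the raw data each step.

*Stitching.*  Patch windows overlap by 50%; each voxel takes the complex
average of `e^{iφ}` over all covering patches that passed the
reciprocity threshold, renormalized to unit modulus; uncovered voxels
keep a flat law.  An optional de-tilt (default on for simulation
studies) removes the best-fit linear ramp — estimated wrap-free from
nearest-neighbour phase differences — since a ramp only translates the
image and is unobservable against a translated ground truth.

*Reciprocity monitoring.*  Input and output laws are estimated
independently (the input side via the transposed matrix) and compared
through `P_in/out = |T̂_in · T̂_out†|/N_u`.  On an *exactly* symmetric
(noiseless) acquisition the two estimates coincide and P ≡ 1; the
product is informative exactly because real acquisitions carry
non-reciprocal noise.  Per-patch thresholding (default 0.9; a lower
threshold is appropriate for the strongly aberrated first steps of a
simulation study) gates which laws are applied; a step that accepts no
patch stops the schedule, and failure at the first step raises a
diagnostic error.

*Confocal filter.*  `R′ = R·exp(−|Δρ|²/(2 l_c(z)²))` with
`l_c(z) = 3 δρ₀(z)` by default, applied to the estimation copy only; it
suppresses the incoherent background that otherwise biases the virtual
guide star and collapses `P_in/out` in noisy data.

## Study conditions

The reference studies (`umi.studies`) fix the following conditions;
they were chosen once to place each estimator in the regime its theory
describes, and the tests run at the stated tolerances.

- **Screen recovery**: 16×16 probe (0.5 mm pitch, 3 MHz, 80% bandwidth,
  28° cone), speckle slab 10×10×4 mm at z ≈ 20 mm, screen rms 1.5 rad
  (≈ 80 ns) with 2 mm correlation length, mild noise; four single-patch
  steps.  Recovery ≥ 0.95 circular correlation, final P ≥ 0.9,
  post-correction RPSF radius within 25% of δρ₀ at all tested depths.
- **Bias scaling / reciprocity relation**: 12×12 probe, screen rms
  0.6 rad, channel noise ≈ 30× the signal rms.  After the ~40 dB array
  gain this leaves focal-domain noise comparable to the signal — the
  attenuation-limited regime of deep trans-cranial imaging — in which
  the input/output estimation errors are noise-dominated and
  independent, the regime where `|δT|² ≃ 1 − P` is derived.  Window
  sizes 2.5–8 mm span > 1 decade of resolution-cell counts N_W; the
  log-log slope of (1 − P) vs N_W is −1 ± 0.3 over ≥ 10 seeds, and the
  truth-referenced error matches 1 − P within 20% in aggregate over
  sweep points with P > 0.5.  (With weak noise the common-mode
  speckle-sampling error — identical on both sides of a symmetric
  matrix — dominates the true error while leaving P near 1, and the
  relation cannot hold; this is a property of exactly reciprocal data,
  not an estimator defect.)
- **Rate recovery**: 16×16 probe imaging a shallow slab (z ≈ 12 mm,
  0.75 mm voxels) so the de-scanned annulus `(6 δρ₀, 10 mm]` is
  populated; injected α_M = α_N = 0.25 recovered within ±0.05.
- **β calibration**: exactly symmetric / anti-symmetric matrices give
  β = 0 / 1 to numerical precision; iid complex Gaussian matrices give
  β = 0.5 ± 0.05 over 100 realizations.

## What the synthetic data does and does not show

The generator reproduces: diffraction-limited focusing through a known
aperture, fully developed speckle statistics, thin-screen aberration
applied reciprocally on both legs, the symmetry split between reciprocal
and non-reciprocal energy, and attenuation-limited noise floors.  It does
*not* model: distributed (volume) aberration or angle-dependent screens,
real multiple-scattering transport (the surrogate only has the right
symmetry and spectro-temporal envelope), reverberation/multiple
reflections between layers, element impulse-response dispersion,
attenuation, or tissue motion.  Passing the studies therefore validates
the estimators' statistical machinery and the pipeline's self-
consistency, not performance on tissue; in particular the bias constants
(coherence factor) of real media can differ substantially.

## Numerical choices and edge cases

- Delay sums are evaluated per depth on a time window covering the delay
  span plus a 1 µs margin; a window outside the recorded axis raises.
- Raw data are stored complex64 (IQ precision); computation is float64.
- Focal points whose cone contains no live element are zeroed and
  flagged in a coverage mask.
- `resolution_3db` on plateau-dominated profiles, `decompose_rpsf` with
  an empty annulus, and β with empty de-scanned support return flagged
  results rather than raising.
- Determinism: every random stage takes an explicit integer seed
  (`numpy.random.default_rng`); repeated runs are bit-identical,
  including the numba-compiled Born sums.
- The IPR global phase is pinned, so laws are comparable across patches;
  piston/tilt are removed only where a translation-invariant comparison
  is intended.

## Known limitations

- Transducer-basis focal-domain correction (without raw data) is
  approximate on small fields of view; prefer the raw-data route or the
  Fourier basis.
- The plane-wave transmit model is narrowband for the aberrated leg;
  strong screens combined with very wide bands would need a full
  per-element synthesis.
- The multi-scale driver re-estimates from the corrected matrix at each
  step (laws accumulate multiplicatively); alternatives that keep
  correlating against the original matrix are not implemented.
- 1D-array emulation assumes the collimated axis is well focused at the
  chosen focal line; away from that depth the emulated PSF degrades, as
  with a physical cylindrical lens.
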