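# Methods

This note documents the physical model, the numerical choices and the
limits of validity of the `ixflim` package.

## Forward model

An ixFLIM acquisition records one TCSPC FLIM frame per interferometer
delay `τ`.  The detected signal is linear in the excitation intensity
(count rates are assumed far below the pulse repetition rate, so photon
pile-up is not modelled), which makes the expected stack a sum of
separable terms

    E[counts](τ, t, y, x) = Σ_terms W(τ) · K(t) · C(y, x).

`W(τ) = ∫ ε(λ) Spec(λ)(1 + V cos(ω(λ)τ)) dλ` is the overlap of a
component's excitation spectrum with the modulated laser spectrum
(trapezoid rule on the laser wavelength grid); `C(y, x)` is its
concentration map; `K(t)` is its emission kinetics convolved with a
Gaussian IRF and scaled by `k φ η` (decay rate × quantum yield ×
detection efficiency).

For a donor–acceptor pair detected in the acceptor channel the rate
equations

    dP_D/dt = −(k_D + k_T) P_D,     dP_A/dt = k_T P_D − k_A P_A

give three kernel terms: the directly excited acceptor (`e^(−k_A t)`, with
the acceptor spectrum), the donor-fed acceptor emission
(`k_T/(k_T+k_D−k_A) (e^(−k_A t) − e^(−(k_T+k_D)t))`, with the *donor*
spectrum — rising with rate `k_T + k_D`), and donor emission leaking
through the detection filter (`c_D^f e^(−k_D t) + c_D^b e^(−(k_T+k_D)t)`,
weighted by `k_D φ_D η_D`).  The degenerate case `k_T + k_D = k_A`
(relative rate difference below 1e−9) is evaluated by its analytic limit
`k_T t e^(−k_A t)`, not by perturbing a rate.

Photon noise is independent Poisson per 4-D bin, drawn from a
`numpy` generator with an explicit integer seed recorded in the stack
metadata.  A `noiseless=True` switch returns the expectation itself for
oracle tests.  Axis order is `[τ, t, y, x]`; times are ns (left bin
edges), delays fs, wavelengths nm, rates ns⁻¹.

### The decay kernel

`exp_gauss_kernel` evaluates `e^(−kt) θ(t) ⊗ G(t; t₀, σ)` through the
complementary-error-function closed form, rewritten with
`erfcx(z) = e^(z²) erfc(z)` where the plain form would overflow:

    f(t) = ½ erfcx((kσ − u)/√2) e^(−u²/2),   u = (t − t₀)/σ   for z ≥ 0,
    f(t) = ½ e^((kσ)²/2 − k(t−t₀)) erfc(z)                    for z < 0.

The two branches are exactly equal analytically; each is used where its
exponent is non-positive, so the kernel is finite for `kσ` beyond 10³.
The companion `t e^(−kt)` kernel (degenerate transfer) is the analytic
`−∂/∂k` of the same expression.

## Reconstruction

The processing chain per `(t, y, x)` is: subtract the mean along `τ`
(suppresses the unmodulated background), take the real part of the
discrete Fourier transform along `τ` on the zero-padded frequency grid
`ω_k = 2πk/(N_pad Δτ)` (padding factor 4 by default — it refines the
frequency *sampling* for smooth resampling, not the resolution), convert
`ω → λ = 2πc/ω` with the Jacobian `dω = (2πc/λ²)dλ`, and resample
linearly onto a uniform wavelength grid.  Amplitude conventions: the scan
is treated as one-sided from the calibrated `τ = 0` (any earlier samples
are discarded), the transform is a cosine transform centred there — with
the origin at zero delay the fringe phase vanishes and the real part
carries the full amplitude, which is the package's resolution of the
phase ambiguity — and the `τ = 0` sample enters with trapezoid weight ½
so it does not bias every frequency bin.  No apodization is applied by
default (preserves component amplitudes); a Hann window is available as a
flag.

**Calibration.**  Zero delay is located as the constructive-interference
maximum of the spectrally integrated reference interferogram (Hilbert
envelope, cross-checked against the raw maximum); the true delay step is
the fringe frequency of the reference at its centre-of-mass wavelength
(zero-padded FFT peak with parabolic interpolation) divided by the known
optical frequency.  An unmodulated reference raises `CalibrationError`
rather than returning garbage.

**Laser normalization.**  The laser spectrum used for division is
obtained by pushing the spectrally integrated reference interferogram
through the *same* operator, so scan-length, visibility, windowing and
Jacobian factors cancel exactly.  Wavelengths where the reconstructed
laser falls below `mask_threshold` (default 0.05 of its maximum,
mirroring the 5 % per-pixel intensity threshold used for image masking)
are flagged invalid and zeroed; division there would only amplify noise.
Normalization is optional — spectral decomposition fits deliberately use
the raw laser-weighted product instead (see below).

**Noise propagation.**  The whole chain is one linear operator
`A[λ, τ]` (mean subtraction included).  Since the input is Poisson,
the per-bin output variance is exactly `(A∘A) @ counts`, computed
alongside the values, plus a per-wavelength one-photon floor
(`mean_τ A²`, the analogue of `max(counts, 1)`) so empty bins are treated
as uninformative rather than infinitely precise.  ROI transient maps sum
this variance, and global fits weight with it by default.  This matters:
with unit weights the per-bin variance tracks the decaying photon flux,
and the information criterion over-selected components on a substantial
fraction of seeds; with propagated weights selection is stable and
lifetime recovery measurably better.

Moment images use the first moment `⟨t⟩ = Σ(t−t₀)F(t)/ΣF(t)` and the
spectral centre of mass restricted to a wavelength window; pixels below
the intensity threshold or with a vanishing denominator are NaN, never an
exception.

## Global analysis

`ixFLIM(t, λτ) = Σᵢ Sᵢ(λτ) e^(−kᵢt) ⊗ irf(t)` is fitted by variable
projection: the spectra enter linearly and are re-solved per wavelength
(batched 3×3-scale normal equations) at every step of a nonlinear search
over the log rates.  Spectra are unconstrained in sign, so rise
components appear as negative amplitudes.  Without explicit starting
rates, a multi-start (8 by default) over log-spaced rates between the
bin rate and the window rate, with seeded log-normal perturbations, is
used and the best candidate kept; results are deterministic given
(map, init, seed).  Rates are reported fastest-first with Jacobian-based
standard errors; components whose lifetimes agree within 5 % with
proportional spectra are merged.  IRF parameters are taken from
acquisition metadata (no joint refinement by default).

Weighting: propagated variance when the map carries it, `1/max(counts,1)`
for raw count maps, unit weights otherwise.  The reduced chi-square is
meaningful (≈1) when bins are reasonably populated; nearly empty bins
dilute it toward smaller values — a known artefact of count-floored
weights, documented rather than hidden.

Model selection fits `n = 1..n_max` and takes the BIC minimum
(`N ln(wRSS/N) + p ln N`, `p = n(1 + n_λ)`); BIC was chosen as the
default because it needs no significance level and is robust at the
photon budgets simulated here.  An F-test alternative is available.  A
residual improvement that is essentially zero (relative change < 1e−9,
e.g. noiseless data at machine precision) caps the model size; a
*negative* improvement — a larger model stuck in a worse local optimum —
merely loses on its own BIC and does not truncate the search.

## FRET quantification

* **Rise time**: `E = 1 − τ_rise/τ_D`, with first-order error
  propagation.  A rise time longer than the donor lifetime yields a
  negative raw efficiency and a warning (no transfer, or a mis-assigned
  component); reported efficiencies are clipped to [0, 1] with the
  pre-clip value retained.
* **Spectral decomposition**: linear least squares of the raw
  (laser-weighted) time-integrated spectrum on
  `{ε_A·Spec, ε_D·Spec}`; fitting the raw product rather than the
  normalized spectrum avoids amplifying noise at the laser edges.  Under
  equal donor/acceptor concentrations `E = w_D/w_A`.  Donor emission
  leaking through the detection filter multiplies the donor weight into
  `E + r(1 − E)`; the caller supplies the single leak ratio `r` (whether
  computed from quantum yields alone or including rate and detection
  factors — both conventions appear in practice) and the estimate is
  corrected as `(E_app − r)/(1 − r)`.  Collinear references and
  non-positive acceptor weights are reported.
* **Per-pixel efficiency imaging**: band integrals of the donor and
  acceptor spectral regions, unmixed with the 2×2 matrix of reference
  band integrals, then `E = w_D/w_A` per pixel; below-threshold pixels
  NaN.
* **Donor quench**: `E = 1 − τ_DA/τ_D` from fitted (for
  multi-exponential donors: amplitude-weighted mean) lifetimes.

**Förster theory.**  `R₀⁶ = 8.79·10⁻⁵ κ² n⁻⁴ φ_D J` with
`J = ∫ α_a(λ) FL_d(λ) λ⁴ dλ` in M⁻¹cm⁻¹nm⁴ (trapezoid rule), giving `R₀`
in Å, converted to nm.  The donor quantum yield is an explicit optional
factor with default 1, since published prefactor conventions differ in
whether they absorb it.  `E = 1/(1 + (R/R₀)⁶)`, inverse
`R = R₀((1−E)/E)^{1/6}`.

**Helix geometry.**  For dyes rigidly attached to the backbone of B-DNA
(0.34 nm rise, 36°/bp twist, both configurable), a dye at base-pair
offset `n` sits at azimuth `n·twist` and height `n·rise`, at a radial
offset `ρ` from the axis; its transition dipole is tangential, tilted
out of the base plane by `±β` — opposite signs for the two dyes because
they ride antiparallel strands.  Disorder is independent wrapped-normal
jitter of each dye's azimuth (`helical_angle_sigma`) and tilt
(`rise_angle_sigma`).  Per Monte-Carlo sample the orientation factor
rescales the isotropic-average Förster radius
(`k_T/k_D = (κ²/⅔)(R₀/R)⁶`) and the reported efficiency is the
ensemble mean of per-molecule efficiencies (static disorder: each
molecule's geometry is frozen on the transfer timescale).  An
`isotropic_kappa=True` mode fixes `κ² = ⅔`, reproducing the hypothetical
freely rotating dye curve used as a reference; note that no large-sigma
limit of the angular jitter is uniform on the sphere, so the isotropic
curve is an explicit mode, not a disorder limit.  `fit_helix_model`
optimizes any subset of (radial offset, tilt, sigmas) by bounded least
squares with deterministic multi-start and common random numbers, so the
MC objective is smooth and the result reproducible from the model seed.
The geometry produces the characteristic non-monotonic efficiency for
internally labelled DNA — at two full turns (20 bp) the dipoles realign
and transfer is enhanced relative to 13 bp — for suitable offsets and
tilts; a least-squares fit to measured efficiencies naturally tracks the
*measured* ordering instead.

## Synthetic scenes and what they do (not) show

The three presets mirror the systems the method was demonstrated on:
free/bound potential-sensitive dye in adjacent capillaries (90 ps/595 nm;
0.5 ns/620 nm + 1.5 ns/632 nm), Cy3–Cy5 dsDNA on beads at 4/12/13/20 bp
separation (donor 0.75 ns, acceptor-on-bead 1.34 ns, transfer rate set by
the per-separation target efficiency, donor leak zero in the
700 nm-filtered channel), and a cell-nucleus scene with free donor
(2.9 ns), acceptor (1.5 ns) and a bound fraction rising at 0.18 ns, the
bound-donor amplitude twice as large in the nucleolus as in the
nucleoplasm.  Acquisition defaults mirror a full measurement (301 delay
steps of 0.75 fs, 50 ps FWHM Gaussian IRF, 256×256 pixels, interference
visibility 1 — the instrument's actual visibility is not published, so
the ideal value is the default and `V` is configurable); tests and the
acceptance script run reduced sizes (32×32, 64 delays, ~10⁶ photons,
512 time bins over 10 ns), which the package treats as ordinary
overrides.

The generator emulates: separable excitation/kinetics physics, Poisson
counting, IRF blur, fringe-calibrated delay axes.  It does **not**
emulate interferometer phase drift or nonlinearity beyond a constant
step-scale factor, detector afterpulsing or dead time, pile-up,
scattering/autofluorescence backgrounds, sample motion or bleaching.
Passing recovery tests therefore demonstrate the correctness of the
processing chain and estimators under the stated noise model, not
robustness to every instrumental artefact of a real microscope.

At 64 delay steps of 0.75 fs the spectral resolution is ~25 nm at
600 nm — enough to separate donor from acceptor bands but not the 12 nm
shift between the two bound-dye species, which the global analysis
distinguishes by lifetime instead; the full 301-step scan (used in the
noiseless round-trip tests) resolves ~5 nm.

## Numerical choices, edge cases

* Spectral integrals: trapezoid rule on the laser grid.
* Zero-budget simulations return all-zero stacks; empty ROIs, overlapping
  unmixing bands, unmodulated references and schema-less containers raise
  typed errors with actionable messages.
* Zero-denominator pixels in moment/efficiency images are NaN-flagged,
  never exceptions.
* `E ∈ {0, 1}` has no finite distance inverse and is rejected.
* All stochastic steps (simulation, fit multi-starts, MC sampling) are
  seeded; identical configuration and seed give byte-identical artifacts.

## Known limitations

* The efficiency-distance inversion assumes a single dominant
  donor–acceptor pathway and the stated `R₀`; multi-acceptor geometries
  are out of scope.
* At very small separations (≲ 6 bp) point-dipole Förster theory itself
  becomes questionable; the helix model will happily extrapolate there
  and simply predicts `E → 1`.
* The donor-quench estimator takes scalar (mean) lifetimes; a full
  multi-component donor decay decomposition is the caller's
  responsibility.
* The reconstruction assumes a uniform (after calibration) delay grid;
  arbitrary jittered delay axes are not supported.
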