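# Methods

## The problem

Optically pumped magnetometers (OPMs) used for wearable MEG are
magnetometer-type sensors, highly sensitive to environmental magnetic
interference that is orders of magnitude larger than neural fields.  Signal
space projection (SSP) with a regular spherical-harmonic interference model
removes such fields, but it assumes every channel reports the field with the
same gain.  Real OPM arrays have non-uniform, and in drifting environments
time-varying, channel gains; a few percent of gain non-uniformity visibly
degrades SSP, and the degradation grows with the harmonic order of the
model.  This package implements plain SSP, a regression-calibrated variant
(CSSP), and the variational-Bayes calibrated variant (VBCSSP) that estimates
the gains jointly with the interference amplitudes.

## Models

**Interference basis.**  External fields inside a source-free sensor volume
are gradients of harmonic potentials regular at the expansion origin.  The
basis matrix `S` has one column per real solid harmonic degree/order pair
(l, m), l = 1..L, m = −l..l, giving N = L² + 2L columns; column (l, m) is
∇(r^l Y_lm) evaluated at each channel position and projected on the
channel's orientation.  We use the orthonormal (fully normalised) real
harmonic convention without the Condon–Shortley phase, evaluated in closed
form (the solid harmonic factorises into a polynomial in (x, y) and a
polynomial in (z, r²), both differentiated analytically).  The convention is
immaterial for the projection — any fixed convention spans the same
subspace — and columns are unit-normalised by default, which also fixes the
effective per-component regularisation of the VB model.  The expansion
origin defaults to the sensor centroid; synthetic helmets use the sphere
centre.  L = 1 spans exactly the three homogeneous fields (homogeneous
field correction).

**SSP** (`ssp_fit`/`ssp_apply`): ê = (I − S S⁺) B.  When N ≤ M the
pseudo-inverse is solved from the normal equations; when the basis is
rank-deficient (N > M, e.g. order 6 on 45 channels) an SVD pseudo-inverse
with relative cutoff 1e-10 is used and a warning is emitted — the fit
proceeds so the known breakdown of SSP in this regime remains observable
rather than being masked by an error.

**CSSP** (`cssp_fit`): per-channel least-squares gains
ĉ_m = ⟨b_m, b̂_m⟩ / ⟨b̂_m, b̂_m⟩ against the SSP interference prediction
b̂ = S S⁺ B, then SSP with the gain-scaled basis diag(ĉ) S.  Channels whose
predicted interference is identically zero get gain NaN and an exclusion
flag rather than a silent zero.

**VBCSSP** (`vbcssp_fit`): the observation model b(t) = C S h(t) + e(t)
with C = diag(c_d), priors h(t) ~ N(0, I), c_d ~ N(0, ρK), and noise
e(t) ~ N(0, λ⁻¹I).  A factorised Gaussian posterior Q(H)Q(c_d) is optimised
by coordinate ascent; λ and ρ are updated by empirical Bayes.  Data are
standardised per channel (mean 0, sd 1) before the fit — gains are
per-channel quantities, and per-channel scaling equalises the effective
signal-to-noise across channels (a single global scale was tried and
recovers gains far worse).  All outputs are mapped back to input units;
channel means are not restored in the cleaned data, since the DC component
belongs to the interference, not to the residual estimate.

## Free energy and hyperparameters

The free energy is the standard Gaussian evidence lower bound

F = E_Q[log N(B | C S H, λ⁻¹I)] − KL(Q(H)‖N(0, I)) − KL(Q(c_d)‖N(0, ρK))
    − (M/2)·log ρ.

The last term is an improper scale hyperprior p(ρ) ∝ ρ^(−M/2).  It is
included deliberately: the empirical-Bayes update used for ρ,
ρ̂ = tr{K⁻¹(Φ⁻¹ + c̄c̄ᵀ)}/(2M), maximises F exactly *with* this term
(without it the maximiser would carry 1/M, not 1/(2M)), which makes every
update in the loop a coordinate-ascent step and the free-energy trace
provably non-decreasing within a rejection round — a property the test
suite asserts.  The λ update λ̂⁻¹ = E_Q‖B − CSH‖²/(TM) needs no such term.
F is used both for convergence (relative change below 0.005% by default)
and for selecting the harmonic order (`select_order`): on simulated data the
converged F peaks at the generating order and falls away smoothly on both
sides, with or without gain error.

## Algorithm details

- **Initialisation**: c̄ = 1 (the no-error belief, matching the
  standardised data scale), Φ⁻¹ = I, H̄ = 0, λ = 1, ρ = 1, K = I unless a
  user SPD matrix is supplied.
- **Negative-gain rejection**: a negative posterior gain is physically
  implausible for a correctly mounted sensor under the harmonic field model
  (it indicates an inverted axis).  After each full iteration, channels
  with c̄_m < 0 are removed and the fit restarts from initialisation on the
  reduced set.  The fit aborts if more than 25% of channels would be
  rejected cumulatively, or fewer than max(N/4, 4) channels would remain —
  that signals model misfit, not a few bad sensors.
- **Scale correction**: H and C are mutually adjustable (only the product
  C S H is data-constrained), so after convergence H is rescaled to match
  the Frobenius norm of the SSP amplitude estimate and c_d divided by the
  same factor.  The cleaned output and the projector are built from the
  converged state and are invariant under this rescaling.  Returned gains
  are de-standardised (multiplied by each channel's sd), normalised to unit
  RMS with nonnegative mean.
- **Sign multi-start**: with N ≥ M the basis spans the full channel space,
  so flipping the sign of any single channel's gain (with H adjusted) is an
  exact likelihood symmetry, broken only weakly by the amplitude prior;
  coordinate ascent from all-positive gains can then converge to
  sign-flipped local optima.  The fit is therefore restarted from several
  sign initialisations — all-ones, the signs of a quick fit with a
  well-determined reduced-order sub-basis, and caller-supplied signs — and
  the solution with the highest free energy is kept.  Free energy
  discriminates these basins sharply (differences of 10³–10⁴ nats on
  5-second benchmark windows).
- **Windowed application** (`windowed_vbcssp`): non-overlapping segments,
  independent fits, cleaned segments concatenated; a trailing segment
  shorter than 2N samples is passed through with a warning.  Negative-gain
  rejection is disabled by default here: a slowly oscillating gain
  legitimately passes through zero inside a window, so a negative
  quasi-static gain is signal to track, not a flipped sensor.  Consecutive
  windows are sign-aligned for continuity (the joint sign of C and H is a
  gauge freedom), and each window passes its gain signs forward as a
  multi-start candidate.
- Floors of 1e-12 on λ⁻¹ and ρ guard the exact-fit and gain-free corner
  cases.  Default cap of 500 iterations per rejection round; non-converged
  fits return with a flag and warning rather than raising.

## Synthetic benchmark

`simulate` reproduces the study conditions: 45 channels (15 tri-axial sites
on a 10-cm upper-hemisphere Fibonacci lattice), T = 10 000 samples, an
order-L_true interference field with unit-norm basis columns and amplitude
coefficients of sd 100× the residual sd (with the residual read as 100 fT,
the interference is 10 pT), static gains ~ N(1, σ_C²) with σ_C up to 0.1,
and a neural residual e = G X from a Sarvas spherical-conductor lead field
(default 1000 tangential dipoles at 0.8 of the sensor radius) scaled so the
pooled sd of e is exactly 100.  The dynamic benchmark runs 100 s at
1000 Hz with per-channel sinusoidal gains A_m sin(2πft + φ_m), f = 0.01 Hz,
A_m ~ N(1, 0.1²), random phases.

What the stand-ins do *not* emulate: the real sensor layout of a published
helmet, a cortical surface source model (our dipoles are random tangential
orientations on a shell), realistic 1/f OPM noise spectra, cross-axis
projection errors, or head movement.  Benchmark numbers are therefore
statistical reproductions — the qualitative ordering of methods and the
magnitudes of shielding-factor drops and correlations, not bitwise values.
One consequence is visible in the scores: residual correlations after
projection depend on how much the source covariance overlaps the harmonic
subspace, so values can shift by a few hundredths under a different source
model.

## Scoring

- Shielding factor SF = 10·log₁₀(var(B)/var(ê)), variances pooled over all
  entries so each condition yields one scalar; +inf is flagged, not
  raised, when the residual is exactly zero.
- Spectral SF: Welch PSD (2-s Hann segments, 50% overlap), channel-averaged
  before the ratio, band-averaged in dB.
- CORR(e): per-channel Pearson correlation of true vs estimated residual,
  averaged over channels; constant channels are excluded with a warning.
- CORR(C): Pearson correlation of gain vectors, rejected channels excluded
  pairwise; a zero-variance truth raises (the statistic is undefined at 0%
  gain error).  `align_sign=True` scores modulo the joint (C, H) → (−C, −H)
  flip — required when true gains are signed, as in the dynamic benchmark,
  where the flip is unidentifiable in principle.
- Lead-field attenuation: per-column dB ratio var(P G_i)/var(G_i).

## Known limitations

- Only diagonal C: crosstalk (off-diagonal) calibration would need extra
  structure (e.g. sparsity within sensors) to stay well posed.
- The gain prior is zero-mean for conjugacy, so positivity is enforced
  heuristically (rejection), not through the prior.
- Residual correlation after high-order projection is intrinsically capped
  (at matched order 5, ~0.45 in this benchmark): the harmonic subspace
  overlaps the neural subspace, and that loss is common to all SSP-style
  projectors.
- The windowed estimator assumes gains are quasi-static within a window;
  windows much shorter than 2N samples are unstable and trigger a warning.
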