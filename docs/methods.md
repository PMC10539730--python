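# Methods

## The signal model

`xecest` treats indirect detection of caged xenon as a two-channel
depolarization of the free hyperpolarized pool under CW saturation.

**Direct channel.** Off-resonance rf at offset Δ = ω_i − ω_A from free xenon
tilts the effective field by θ = arctan(ω₁/|Δ|). The transverse part of the
magnetization is dephased by rf inhomogeneity and R₂; the spin-locked part
relaxes at the mixed rate λ_direct = R₁ᴬcos²θ + R₂ᴬsin²θ. This term exists
without any exchange and sets the Z-spectrum baseline. At low field it is
the dominant design constraint: with free and caged xenon only ~144 ppm
apart at 12.09 MHz, ω₁ = 64.7 rad/s already erodes the baseline by ≈3 % over
3 s, and stronger saturation quickly destroys the contrast.

**Exchange (CEST) channel.** Saturating the dilute caged pool removes its
polarization at a rate that, carried through exchange, depolarizes the free
pool. On resonance with the cage the rate is λ_on = f·k_out·ω₁²/(ω₁²+k_out²),
and as a function of rf offset it is a Lorentzian centred on the cage shift
with FWHM Γ = 2√(ω₁²+k_out²). These expressions assume a dilute pool
(k_in = f·k_out ≪ k_out) and fast exchange relative to bound-pool transverse
relaxation (k_out ≫ R₂ᴮ). Multiple cages contribute additive Lorentzians —
valid for independent dilute pools.

**Signal equation.** Hyperpolarized magnetization has no thermal reservoir
to recover toward on the experiment's timescale, so relaxation drives every
component to zero and Z(ω_i, ω₁) = M₀ᴬ·e^(−λ t_sat). A simplified
"high-field" variant (λ = R₁ᴬ + Σ λ_CEST) is available behind a flag; it
converges to the full rate as |ω_i−ω_A|/ω₁ → ∞ with a relative error
≈ (R₂ᴬ−R₁ᴬ)·(ω₁/Δ)²/λ, so how fast it converges depends on R₂ᴬ/R₁ᴬ.

The population-weighted relaxation rates (1−f)R₁ᴬ + f·R₁ᴮ (and likewise for
R₂) are computed but *not* used in λ_direct by default: at f of a few
percent the correction is far below every other uncertainty. A
`weighted_relaxation` flag switches to the exact weighted rates.

## Units and conventions

All internal rates and angular frequencies are rad/s; chemical shifts are
ppm only at API surfaces, converted through `FieldConfig`, which owns the
Larmor frequency (MHz) and the reduced gyromagnetic ratio γ̄ = 11.79 MHz/T.
The sign of γ (negative for ¹²⁹Xe) is stored separately and used only where
it flips an axis (gradient encoding/decoding); scalar bounds use the
magnitude. B₁ in µT is a derived display value, ω₁/(2πγ̄). Note that the
conversion is configuration-driven: published ω₁↔B₁ pairs are not always
exactly consistent with a single γ̄, so rad/s values are treated as primary.

## Bloch–McConnell oracle

`xecest.bloch` builds the full linear generator over (x, y, z) of every pool
in the rotating frame of the rf carrier: precession at each pool's offset,
CW rf of amplitude ω₁ along a fixed transverse axis (the CW phase is
irrelevant to z-dynamics), relaxation toward zero, and exchange coupling
k_in/k_out applied to all three components. Propagation is by exact matrix
exponential (`scipy.linalg.expm`); a stepped mode exists for trajectory
sampling and agrees with the exact product to <10⁻⁶ relative. The effective
depolarization rate is extracted from the endpoint, −ln(z_A(t)/M₀ᴬ)/t,
matching the single-exponential signal model; a multi-time-point log-linear
fit is available as a diagnostic for multi-exponential behaviour.

Because bound-pool relaxation rates are rarely known, defaults are
R₁ᴮ = R₁ᴬ and R₂ᴮ = k_out/100, i.e. comfortably inside the analytic model's
validity region. The oracle-equivalence test grid
(f ∈ {0.01, 0.03, 0.05} × k_out ∈ {30, 50, 100} s⁻¹ × ω₁ ∈ {30, 64.7, 120}
rad/s, t_sat = 1 s, offsets 24–80 ppm at 12.09 MHz) keeps the worst-case
relative deviation of the two Z spectra under 10 %; pushing R₂ᴮ toward k_out
makes the deviation grow, which the tests assert qualitatively. Because the
analytic and numerical rates differ by O(R₂ᴮ/k_out, k_in/k_out) in λ, the
*Z-domain* deviation scales with λ·t_sat — deep dips amplify small rate
errors — which is why the comparison uses a 1 s saturation.

## UFZ simulator

The single-shot experiment is modeled as:

1. **Density profile.** For a transverse gradient on a cylindrical tube the
   1-D projection is the chord length ρ(x) ∝ √((r/2)²−x²) on |x| ≤ r/2
   (r = inner diameter, 0.43 cm by default), normalized to unit maximum.
2. **Encoded saturation.** During saturation under G_sat the rf appears
   shifted by −γG_sat·x at position x, so λ is evaluated *continuously* at
   every x with the full analytic rate (direct + all Lorentzians). No hard
   slab/slice approximation is made — the Lorentzian already encodes the
   spectral selectivity and naturally produces finite dip widths.
3. **Profiles.** off(x) = off_scale·ρ(x), on(x) = ρ(x)·e^(−λ(x)·t_sat), each
   optionally multiplied by independent per-point relative Gaussian noise
   from a seeded generator (`numpy.random.default_rng`). `off_scale`
   (default 1.0) models the intensity rescaling between the two acquisitions
   of a hyperpolarized experiment; no published value exists for it.
4. **Readout.** Acquisition under G_acq is an ideal position→frequency map
   ν(x) = γG_acq·x, expressed in apparent ppm at the configured Larmor
   frequency; the apparent axis reverses when the gradients' effective signs
   differ. A true splitting Δδ between two cages appears as
   Δδ·|G_acq/G_sat|. No FID/k-space simulation of the echo readout is
   attempted, and the rf coil's excitation–detection spatial profile is not
   applied (flat sensitivity); both are out of scope.

**Dip-position measurement.** Dip centers are located on the pointwise ratio
Z(x) = on/(off/off_scale), not on the off−on difference: the difference is
modulated by the density envelope, which drags apparent dip positions toward
the tube center (strongly so for saturated, flat-bottomed dips near the
envelope edge), whereas the ratio removes the envelope exactly and its
minimum coincides with the encoded resonance. Minima are refined to sub-bin
precision by a three-point parabolic fit.

Default spatial discretization is 512 points across the tube — about 12
points across the FWHM of a benchtop-condition dip, comfortably above the
8-point minimum the fitter requires, while keeping a full simulated
experiment in the millisecond range.

## Fitting and inversion

Fitting operates in the rate domain λ̂ = −ln(on/(off/off_scale))/t_sat
(rates are additive, so baselines separate linearly; and the envelope
divides out exactly, including its noise realization in the off trace).
Points where the envelope falls below 10 % of its maximum are excluded —
the log-ratio variance diverges at the chord edges. Non-positive ratios
inside the support (possible at high noise in deep dips) are clipped to the
smallest positive ratio present and reported via a warning.

The model is baseline + Σ Lorentzians, fitted with bounded least squares
(`scipy.optimize.curve_fit`). Initialization: baseline from the median,
center at the largest baseline-subtracted extremum, width from the
half-height crossing, amplitude from the height; for multi-component fits
each initialized peak is subtracted before seeking the next. A fit whose
amplitude does not exceed three residual standard deviations is flagged
degenerate. Parameter uncertainties come from the least-squares curvature
(covariance) only; no bootstrap.

Inversion is the exact algebra k_out = √(Γ̂²/4 − ω₁²),
f = λ̂_on(ω₁²+k_out²)/(k_out·ω₁²). It requires Γ̂/2 > ω₁; at or below that
boundary the exchange broadening is not separable from rf broadening and an
`UnidentifiableRegimeError` is raised rather than clipping. Uncertainties
are propagated by the delta method. On noise-free synthetic rate traces the
round trip is exact to float tolerance; on the full noisy UFZ pipeline
(2 % relative noise, 20 replicate seeds, benchtop conditions) the median
k_out error is under 1 % — far inside the 20 % internal quality bar. These
bars characterize the simulator's own noise model, not any claim about real
1 T data, where coil-profile corrections would be needed first.

## Design calculators

* **Gradient bound:** G_sat < |ν_A−ν_B|/(γ̄·d) keeps the encoded saturation
  width inside the free/bound splitting. The splitting may be passed
  directly in Hz (the conventional rounded 1800 Hz at 12.09 MHz yields
  35.5 mT/m for d = 0.43 cm).
* **Regime labels** compare ω₁ to k_out per the λ_on formula: ≥10·k_out
  "saturated" (within 1 % of the ceiling f·k_out), ≤k_out/10 "parabolic"
  (within 1 % of (f/k_out)ω₁²), otherwise "intermediate" (exactly half the
  ceiling at ω₁ = k_out). Published regime lists sometimes compare ω₁ to
  f·k_out instead; the formula itself puts the half-maximum at ω₁ = k_out,
  so that is what the labels follow.
* **ω₁ scan:** "contrast" is operationalized as direct-only baseline minus
  dip minimum (normalized by M₀ᴬ), and "resolved" as every adjacent dip pair
  having a saddle at least 10 % of the deeper dip above both minima. The
  score is min-dip-depth × resolved, and the recommended window is all ω₁
  within 90 % of the best score — a deliberate convention that turns a
  qualitative "best compromise" judgment into something testable. On the
  benchtop two-cage mixture it recommends ≈70–170 rad/s, overlapping the
  50–150 rad/s band a practitioner would pick by eye from the spectra.
* **t_sat trade-off:** dip depth (same definition) versus t_sat at a weak-rf
  working point, against a reference depth evaluated at a strong-rf working
  point that may sit on a different field/relaxation configuration; reports
  the smallest t_sat reaching ≥90 % of the reference. Note that with the
  standard benchtop/high-field parameter pairs the 90 % crossover falls near
  1.5 s, and by 3 s the weak-rf dip is ≈11 % *deeper* than the reference —
  "three times the high-field duration" recovers the reference depth with
  margin rather than just reaching it. Depth is non-monotonic in t_sat at
  fixed ω₁ (the baseline decays too), peaking near
  t* = ln((λ_dir+λ_on)/λ_dir)/λ_on ≈ 3.8 s for the benchtop point.

## What the synthetic data do and do not show

The generator reproduces: chord-shaped envelopes, gradient-encoded dip
positions and their mirror/invariance symmetries under gradient sign flips,
the gradient-ratio magnification of splittings, rate-additive multi-cage
dips, and seeded per-point relative Gaussian noise. It does not reproduce:
coil excitation–detection profiles, B₀/B₁ inhomogeneity, readout line-shape
effects, shot-to-shot polarization variation, or radiation damping. Passing
recovery tests therefore demonstrate the correctness and noise robustness of
the estimator chain, not field-readiness against instrument systematics.
Experimentally observed figures of merit (SNR, linewidths, absolute
polarization, micromolar detection limits) are instrument properties and are
deliberately not simulated.

## File formats

Configs are flat YAML with units in key names (`omega1_rad_s`,
`gsat_t_m`, ...); unknown keys are rejected so a typo cannot silently
default. Traces round-trip bit-identically through CSV (17 significant
digits) and value-identically through a minimal JCAMP-DX dialect
(single block, AFFN `XYPOINTS=(XY..XY)` on write; `XYDATA=(X++(Y..Y))`
also accepted on read). Compressed JCAMP forms (SQZ/DIF) are not supported.
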