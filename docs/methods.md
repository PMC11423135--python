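# Methods

## The measurement principle

Chlorophyll *a* fluorescence (ChlF) from a leaf is a side product of PSII
charge separation.  Upon a dark-to-light step, the fluorescence yield rises
as the first quinone acceptor Q_a accumulates in its reduced state, because
closed centres (Q_a⁻) cannot quench excitons photochemically.  The very
first step of this OJIP rise is light-limited: its rate constant is
`k = 1/τ = σ(λ)·I`, with σ(λ) the cross-section for PSII photoactivation
(m² mol⁻¹) and I the photon flux density (E m⁻² s⁻¹).  A measured τ plus a
known σ therefore yields absolute light intensity, `I = 1/(σ·τ)`.

Assumptions inherited by everything downstream:

* fluorescence is proportional to the reduced-Q_a fraction (connectivity
  between PSII units, PSI contribution and quenching on the sub-second
  scale are neglected);
* the quantum yield of the initial step is wavelength-independent, so the
  wavelength dependence of σ is that of the fluorescence excitation
  spectrum;
* the leaf is healthy and dark-adapted — operationally,
  `(F_m − F₀)/F_m ≥ 0.75` (the maximum PSII photochemical quantum yield
  of healthy material is about 0.75–0.84).  Estimates from traces below
  the threshold are still reported, flagged `qc_pass = False`.

## Three-stage extraction of τ

The rise is multiphasic, so a single fit over the whole transient would
mix the photochemical step with slower acceptor-side kinetics.  The
pipeline (`OJIPRiseFitter`) proceeds as follows.

1. **Conditioning.**  The illumination onset is detected from the dark
   baseline (first crossing of mean + 5 SD sustained for 5 samples,
   then walked back to the last sample at or below the baseline mean —
   without the walk-back, detection on slowly rising stretched
   exponentials is biased late by ~0.1 τ at 2 % noise).  F₀ is the median
   of the 10 samples after onset.  The trace is re-zeroed at the onset,
   truncated at the (lightly smoothed) maximum F_m, smoothed with a
   centred moving average, and logarithmically subsampled (200 samples
   per decade, bins anchored at the first positive timestamp, which makes
   the rule sampling-rate independent and idempotent).
2. **Stage 1** fits `F(t) = F₀ + Σᵢ Aᵢ(1 − e^(−t/τᵢ))^sᵢ` (three
   components, window 50 smoothing) with bounds Aᵢ ≥ 0,
   τᵢ ∈ [10⁻⁷ s, duration], sᵢ ∈ [0.3, 5].  τ starts are data-driven: the
   times at which the rise crosses 25/50/75 % of its amplitude.  Up to
   three jittered restarts run only if the incumbent fit failed, explains
   less than 99.5 % rms of the rise, or parked a non-negligible component
   below the time resolution.  Components are sorted by τ; the fastest
   component that is *resolvable* (τ ≥ half the first sampled time) and
   carries ≥ 5 % of the total amplitude defines τ₁.  The amplitude rule is
   physical — the photochemical step dominates the rise — and prevents
   noise-latching: without it, ~1 %-amplitude sub-µs artefacts capture τ₁
   in roughly one fit out of ten at 2 % noise.
3. **Stage 2** refits a single stretched exponential on [0, 3 τ₁]
   (window 10 smoothing) with the exponent frozen at s = 1.24.
4. **Stage 3** refits on [0, 5 τ] with F(0), A, τ and s all free
   (s ∈ [0.5, 3]), starting from the stage-2 values.  Freeing s is what
   makes the stage non-redundant; on non-convergence the stage-2 result is
   returned flagged `stage3_failed`.

Numerical choices: ordinary (unweighted) least squares on the smoothed,
subsampled points; τ is optimized in log₁₀ space with analytic Jacobians;
trust-region-reflective with xtol 10⁻⁸ and a 500-evaluation budget per
stage-1 start (converged fits use well under 100; a larger budget only
lets unconverged starts wander).  Everything is deterministic given the
input and the restart seed.  A fitted τ below 5× the configured instrument
rise time is flagged `instrument_limited`; stage-2/stage-3 disagreement
beyond 3× is flagged `stage_disagreement`.

Measured performance (the acceptance suite recomputes this): on noiseless
stretched-exponential rises with s = 1.24 and τ from 50 µs to 50 ms the
pipeline recovers τ to better than 0.1 %; at 2 % Gaussian noise the median
error over seeds stays below 5 %, dominated by onset-detection bias rather
than by the least squares.

## Cross-section calibration

With an intercept-bearing linear model `1/τ = σ·I + k` (the two-state
kinetics below predicts exactly that; `through_origin=True` gives the
strict proportionality reading), σ is estimated by OLS over at least seven
intensity levels.  QC-failing points are discarded first (reason
`qc_fail`), then one outlier pass removes at most two points with
studentized residual |z| > 2 (reason `z_outlier`) and the model is refitted
once — no iterative trimming.  The slope SD is the standard OLS standard
error.  Intensities are converted to E m⁻² s⁻¹ internally so the slope
lands in m² mol⁻¹.  `aggregate_sigma` gives the mean ± SD over leaves.

## Wavelength transfer and broadband scaling

σ(λ) = ε_norm(λ)·σ(470), with ε_norm the excitation coefficient normalized
to 1 at 470 nm.  The packaged default spectrum is a **synthetic
reconstruction**: piecewise-linear through the four tabulated anchors
ε_norm = 1.0, 1.0, 0.2, 0.4 at 405, 470, 550, 630 nm, held flat on
[400, 405] and [630, 650] nm, anchored at the species-averaged
σ(470) = 1.1 × 10⁶ m² mol⁻¹.  Between the anchors the true spectrum is
structured (chlorophyll/carotenoid bands), so users with a measured
excitation spectrum should load it via `build_spectrum_from_excitation`
(any anchor wavelength works; re-anchoring is consistent by construction).
Interpolation is linear; wavelengths outside 400–650 nm are a hard error —
σ is not validated there.  Retrieval attaches a factor-two interval (the
leaf-to-leaf σ dispersion) rather than propagating the OLS slope SD, and
warns above the validated photon flux I_sup = 10⁻² E m⁻² s⁻¹.

For a broadband source with normalized emission spectrum j(λ)
(trapezoidal integral 1), the measured rate integrates the action
spectrum, `1/τ = S_I·AS` with `AS = ∫ σ(λ) j(λ) dλ`, so one τ scales the
whole spectrum: `I(λ) = S_I·j(λ)`, `S_I = 1/(τ·AS)`.  Integrals use the
trapezoid rule on the union grid of both inputs.  Emission outside σ's
validity window is excluded from AS and j is renormalized over the
overlap, so S_I refers to the *in-range* photon flux; the out-of-range
fraction is reported (`fraction_in_range`) instead of being silently
integrated against an undefined σ.  Spectra extending beyond 665 nm are
flagged `emission_overlap` (they overlap the ChlF detection band).

## The PSII simulator

The synthetic-data generator is first-class code and the ground truth for
every fitting/calibration test.

**Reduced model** (two states): photoactivation σI against a lumped decay
k gives the closed form
`f(t) = σI/(σI + k)·(1 − e^(−(σI+k)t))`, `τ = 1/(σI + k)`.
The lumped k defaults to 10² s⁻¹ — the order of the intercept observed in
1/τ-vs-I calibration series; it is an effective constant at the
measurement's time scale, not the microscopic recombination rate.

**Full model** (two-electron gate): six PSII states
{Q_aQ_b, Q_a⁻Q_b, Q_aQ_b⁻, Q_a⁻Q_b⁻, Q_aQ_b²⁻, Q_a⁻Q_b²⁻} and a shared
plastoquinone pool.  Photoactivation at σI from every oxidized-Q_a state;
recombination k_r from Q_a⁻Q_b (optionally from all Q_a⁻ states);
electron transfer k₁/k₋₁ (Q_a⁻Q_b ⇌ Q_aQ_b⁻) and k₂/k₋₂
(Q_a⁻Q_b⁻ ⇌ Q_aQ_b²⁻); exchange of doubly reduced Q_b with the pool at
k₃/k₋₃ and k₄/k₋₄, with both directions scaled by the relevant pool
fraction (forward by PQ_ox/pool, reverse by PQ_red/pool — the reverse
scaling is required for pool-count positivity and is a modelling decision,
as is the k₃/k₄ wiring; protonation of Q_bH₂ is neglected).  Defaults:
σ = 10⁶ m² mol⁻¹, k_r = 10⁴, k₁ = 5×10³, k₋₁ = 2×10², k₂ = 1.5×10³,
k₋₂ = 5×10¹, k₃ = k₄ = 10², k₋₃ = k₋₄ = 5×10¹ s⁻¹ — literature orders of
magnitude for PSII.  The pool size (7 PQ per PSII) is a typical literature
magnitude, fully configurable.  Integration: LSODA, rtol 10⁻⁸/atol 10⁻¹⁰,
from the dark-adapted state (all centres Q_aQ_b, pool oxidized).
Fluorescence maps linearly from the reduced-Q_a fraction
(F₀ level 1000, F_m level 5000, giving the healthy QC ratio 0.8).

Acquisition artefacts are applied after the kinetics: an exponential LED
turn-on (first-order IIR filter on the uniform grid) and additive Gaussian
noise with an explicit seed recorded in the trace metadata.  Calibration
datasets adapt each trace's duration to 25× its expected τ (clipped to
[2 ms, 1 s]) at a fixed point budget, and offset seeds by the series index
so duplicate intensities get distinct noise.

**Known systematic of the full model.**  Its initial fast phase has rate
σI + k_r + k₁ and fractional amplitude σI/(σI + k_r + k₁): with the
default rate constants, the initial step only carries measurable amplitude
once σI is comparable to k_r + k₁ ≈ 1.5×10⁴ s⁻¹.  In that regime a fitted
1/τ-vs-I series is linear with slope within ~20 % of σ (the offset from
recombination/transfer is the documented systematic); at much lower σI the
pipeline locks onto slower acceptor-side phases instead.  Real leaves show
near-proportional 1/τ-vs-I down to much lower fluxes, so the full scheme
with these illustrative constants is a structural testbed (phase
structure, conservation laws, model reduction), not a quantitative leaf
emulator — which is why calibration accuracy claims rest on the reduced
model.

## What the synthetic data does and does not show

The generators emulate the kinetic shape of the rise, acquisition rate and
duration, baseline pre-trigger, shot-noise-like additive Gaussian noise
and LED turn-on lag.  They do not emulate baseline drift, detector
nonlinearity, flicker in the light source, leaf heterogeneity within the
spot, anthocyanin screening (non-green leaves are out of scope), NPQ or
photoinhibition beyond 1 s.  Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not field accuracy
on arbitrary leaves; the biological dispersion of σ is carried by the
factor-two interval on every retrieval.

## Problem sizes used by the test and acceptance runs

Synthetic traces use 1.2–2×10⁵ samples (the rule set is
sampling-rate independent; MHz-length traces work identically but add
nothing to the checks), 4 τ decades × 10 noise seeds for recovery
statistics, 9-point calibration series, and 2×10⁴–2×10⁵-point ODE grids.
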