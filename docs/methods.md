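# Methods

This note documents the models, estimators, numerical choices and known
limitations of the package, in the order data flows through the pipeline.

## Quasi-linear membrane model

The membrane admittance, normalized to leak, is

y(f) = γ_R + iωτ + μ_n/(1 + iωτ_n) + μ_h/(1 + iωτ_h),  ω = 2πf,

with α = Re y and β = Im y.  This is the standard two-process quasi-linear
form: each voltage-gated conductance linearized about the holding potential
contributes a first-order term μ_k/(1 + iωτ_k), negative μ for regenerative
(amplifying) currents such as the persistent sodium current and positive μ
for restorative (resonating) currents such as HCN.  We treat the complex
form as normative; the real/imaginary split follows from it (squares in the
denominators of α, minus signs on the μτ terms of β).

Parameters and units: μ_n, μ_h, γ_R dimensionless; τ, τ_n, τ_h in ms; the
impedance scale Amp in GΩ.  Validity requires γ_R + μ_n + μ_h > 0 (DC
stability of the linearized membrane); construction rejects violations.
Typical fitted values for cholinergic interneurons are μ_n ≈ −4 … −1,
μ_h ≈ 0.5 … 3.5, τ_n ≈ 10–60 ms, τ_h ≈ 0.4–9 s, γ_R ≈ 2.6–5.9, τ ≈ 17–45 ms
(see `qlin.presets`).

Phase conventions: all phases are in cycles (argument / 2π), positive when
the response lags the drive.  The somatic phase is arg y / 2π, in
(−0.5, 0.5); a capacitive membrane has positive phase (clamp current leads
the voltage command), and a resonant membrane has a negative lobe below the
impedance peak.  It can be shown (and the tests verify) that the phase zero
crossing sits at a slightly lower frequency than the impedance peak.

## Semi-infinite cable under partial illumination

A homogeneous quasi-linear semi-infinite cable, voltage-clamped at the
soma, transfers current injected uniformly over the electrotonic extent
[0, r] with the factor (1 − e^(−γr))/γ, γ = √(α + iβ) = p + iq.  Branch
choice: γ is the principal square root with p > 0; q inherits the sign of
β.  This is required for the semi-infinite solution to decay with distance
and for the resonant (β < 0) regime to yield the observed negative phases.
The dendritic phase delay φ_d and amplitude |1 − e^(−γr)|/|γ| follow; the
two algebraic forms of φ_d (difference of arctangents vs. −arg of the
complex transfer) agree to 1e−12 and both are exercised in tests.
Channelrhodopsin kinetics multiply in series: the full optogenetic phase is
φ_C + φ_d, with φ_C = (1/2π)·atan2(ω(τ_r+τ_d), 1 − τ_rτ_d ω²) continuous
in f and passing through 0.25 cycles at the denominator zero.

The amplitude-vs-extent monotonicity ("more membrane illuminated, more
current") holds at the sub-resonant frequencies used in the protocols;
at large ωτ the oscillatory part of e^(−γr) can make it non-monotone, so
it is not asserted globally.

## Time-domain oracles

`simulate_isopotential_clamp` integrates the state-space realization
i = (γ_R v + τ dv/dt + w_n + w_h)/Amp, τ_k dw_k/dt = μ_k v − w_k, with
exact exponential updates of w_k (trapezoidal in v), implemented as IIR
filters so 10⁶-sample traces are cheap.  `simulate_cable_clamp`
discretizes the cable PDE on N ≥ 50 compartments with a Dirichlet
(clamped) soma and sealed far end, advancing the stiff diffusion part with
Crank–Nicolson (one sparse LU factorization per run) and the slow gating
variables exponentially.  The step-size guard dt < min(τ active)/20 uses
only time constants whose μ is non-zero.  A sealed end at L = 5
electrotonic lengths stands in for the semi-infinite cable (end effects
decay as e^(−2pL)); the default refinement N = 400, L = 5 reproduces the
closed-form phases within 0.005 cycles over 0.2–20 Hz, with monotone
convergence under refinement (tested at three levels).  ChR2 photocurrent
is the convolution of the suprathreshold LED command (threshold 40 mV of
driver voltage) with the unit-area difference-of-exponentials kernel, with
an inward (negative) sign — which is why the downstream estimator applies
the half-cycle antiphase correction.

## Sweep protocols and the cross-correlation estimator

Protocols are concatenated single-frequency sinusoids; each segment's
duration is the smallest of {3 s, 5 s} holding a whole number of cycles
(falling back to the fewest whole periods totalling ≥ 3 s).  The exact
grid within 0.2–20 Hz is a configuration choice; the default is
{0.2, 0.4, 0.6, 0.8, 1, 1.4, 2, 3, 4, 5, 7, 10, 12, 15, 18, 20} Hz.

Per segment the estimator discards the first full cycle as a settling
transient (when more than one is available — the 0.2 Hz segment holds
exactly one period and is used whole; the residual settling of the slow
restorative gate leaves a ≤ 0.01-cycle bias there, which is a property of
the protocol, not of the estimator), mean-subtracts, and computes the
circular mean-lagged-product CCF over the remaining whole cycles.  The
phase is f × (lag of the CCF peak), with parabolic sub-sample refinement,
the search limited to ± half a period and exact ties broken toward smaller
|lag|.  Magnitude: electrical |Z| = A²/(2·maxCCF) with A the measured
command amplitude — normalized so a pure resistor R is returned exactly —
and optogenetic magnitude = response amplitude per unit LED command
= 2·maxCCF/A².  Sign conventions: the electrical phase is the negative of
the response lag (so it matches arg y directly); LED phases subtract 0.5
cycles because the photocurrent is inward.  A raw-lag convention is also
exposed for diagnostics.

## Fitting

`SomaModel` and `CableModel` minimize squared phase residuals (in cycles,
equal weight per frequency) with `scipy.optimize.least_squares` under the
box bounds μ_n ∈ [−20, 0] (tightened to keep γ_R + μ_n + μ_h > 0),
μ_h ∈ [0, 20], τ_n, τ_h ∈ [1, 2·10⁴] ms, τ ∈ [1, 500] ms, r ∈ (0, 5];
time constants and r are searched in log₁₀ space.  Twenty Latin-hypercube
starts (seeded) guard against local minima; the best solution, its
Jacobian-based standard errors, and the start index are reported.
Magnitude can be fitted jointly (log-magnitude residuals, weight λ,
default 0) with the impedance scale profiled out analytically; phases are
the better-conditioned observable and are the default loss.

Identifiability: arg y is exactly invariant to scaling (γ_R, μ_n, μ_h, τ)
by a common factor, and a free impedance scale absorbs the same factor in
|Z|; in the cable model the analogous trade is between that scale and r.
γ_R is therefore a *fixed* input to the fit (from a DC input-resistance
measurement, or a convention of 1), and the remaining parameters are then
well identified: noiseless round trips recover every published parameter
set to better than 1% (somatic) and 5% (cable).  Proximal and full-field
illumination conditions are fitted independently, matching the published
per-condition parameter tables; a shared-membrane joint fit is not
implemented.

ChR2 kinetics are fitted separately from pulse-averaged photocurrents with
the same multi-start machinery; τ_r < τ_d is enforced by parameterizing
(log τ_r, log(τ_d − τ_r)).  The difference-of-exponentials kernel is
implemented decay-minus-rise, A(e^(−t/τ_d) − e^(−t/τ_r)), so transients
are positive for positive A.

Curve-level comparison uses ANCOVA on the natural logarithm of frequency:
y ~ ln f × group by OLS, type-II F-tests for the group offset and the
group × ln f interaction (statsmodels).

## Calcium spike-triggered analysis

STAs are means of ΔF/F₀ segments aligned to somatic spike times, using
only spikes with complete windows (default 0.2 s pre / 0.6 s post) and
subtracting the mean of the 200 ms pre-spike baseline.  The transient
amplitude is the peak of a fitted difference-of-exponentials curve — less
biased under noise than the raw maximum (verified by simulation).  The
distance profile is a 35 µm centered moving average of amplitude vs.
distance, evaluated at the data points, with edge windows shrinking rather
than padding.  The decay onset ("breakpoint") is operationalized as the
first crossing of the smoothed profile 10% below the plateau median, with
linear interpolation between the bracketing points; on generator output
with a 70 µm breakpoint it returns 70 ± 10 µm at default noise.  The
proximal/distal comparison takes per-cell medians on each side of the
70 µm boundary, reports the median per-cell percentage difference, and
tests proximal vs. distal medians with the two-sided Wilcoxon rank-sum.

## Sleep-LFP events and conditional rates

Slow waves: zero-phase 2nd-order Butterworth band-pass 0.5–4 Hz
(order unstated in the source protocols; zero-phase filtering preserves
peak times), candidate half-waves between consecutive zero crossings,
durations kept in [0.25, 2] s, both polarities admitted with amplitude
|extremum|, artifact rejection above mean + 5 SD of the candidate
amplitudes, and retention of exactly ⌊0.3 × candidates⌋ — the top 30% by
amplitude.  Spindles: 10–17 Hz band-pass, Hilbert envelope, core threshold
mean + 3 SD, boundaries at mean + 0.5 SD, durations 0.5–3 s, and a 20–30 Hz
control-band veto at 4.5 SD; the reported waveform uses a 4-pole 4–25 Hz
Butterworth.  All thresholds are SD-relative, so detection is invariant to
an overall amplitude scale.  SD baselines are computed over the
sleep-stage-masked signal when a mask is provided.

Conditional rates are peri-trigger histograms (default ±2 s, 20 ms bins)
in spikes/s.  The 99% band is the [0.5, 99.5] percentile range of the rate
values in the flanking bins (|lag| ≥ 1 s), pooled across triggers and
computed with outward-rounding percentiles; under a stationary Poisson
train the per-bin excursion probability is ≈ 2/(n_flank + 1) ≤ 2%
(calibrated over 200 simulations in the tests).  Per-bin pooling is our
operationalization of "the distribution of conditional rates 1 s before
and after the peak"; a per-trigger resampling null would be wider.

## Synaptic measures

Amplitudes are measured on the across-trial mean trace: mean peak within
5–50 ms post-stimulus minus the mean baseline in the 10 ms before the
stimulus.  The mean trace is smoothed with a 2 ms boxcar before
peak-picking; without it the maximum of a noisy trace is biased upward by
the noise (≈ +7% at 25 trials of 0.3 mV noise), while the window costs
< 1% of a 2–20 ms-kinetics peak — the residual bias is below 0.5%.  EPSP
mode rejects trials crossing −20 mV (spikes) before averaging and reports
the count.  The paired-pulse ratio re-measures the second-pulse baseline
in the 10 ms before the second stimulus, removing most of the residual
first-response decay (a ≤ 1% bias remains for 20 ms decay kinetics at the
100 ms interval).  Drug effects are per-cell percentage changes of the
mean amplitude, median across cells, with a two-tailed Wilcoxon
signed-rank test on the (pre, post) pairs.

## Synthetic data: what it emulates, and what it does not

Every generator is a pure function of (configuration, seed); identical
inputs give bit-identical data, and the generating parameters ride along
as a ground-truth record.

* Electrical sweeps: exact membrane responses plus additive white current
  noise (5 pA default) — no electrode artifacts, series-resistance error
  or slow drift.
* Optogenetic sweeps: compartmental-cable responses to LED commands riding
  on the 40 mV driver threshold (offset = threshold + amplitude, so the
  trough of the command just reaches threshold), inward photocurrents,
  one membrane truth per proximal/full-field pair.  ChR2 kinetics default
  to τ_r = 2 ms, τ_d = 18 ms (literature-typical for ChR2(H134R));
  desensitization and intensity nonlinearity are not modelled.
* Calcium line scans: pacemaker-like spiking (gamma ISIs, CV 0.1, 1 Hz),
  alpha-function transients (τ_r 20 ms, τ_d 250 ms), white indicator
  noise, and a trapezoidal amplitude profile — rise to 20 µm (the
  surface-to-volume effect of thick proximal dendrites, generated
  phenomenologically), plateau to 70 µm, then a linear decay of
  0.3 %ΔF/F₀ per µm chosen so the decay completes by ~130 µm, consistent
  with reported full invasion ranges.  60 sites pooled over 8 cells.
  Dye buffering and z-drift are not modelled.
* Sleep LFP: 1/f (spectrally shaped) background, planted half-cosine slow
  waves (0.8 s, 8 background SD) and Hann-windowed 13 Hz spindle bursts
  (1 s, 6 SD).  The slow-wave plant rate (0.45 Hz over 300 s) is chosen so
  planted events form roughly the top third of all qualifying background
  half-waves: since the detector by construction retains exactly the top
  30% by amplitude, this is the regime in which the retained set coincides
  with the planted ground truth and recall/precision are well defined.
  TAN-like trains are inhomogeneous Poisson with a biphasic modulation at
  slow-wave peaks (Gaussian dip of 0.8× baseline, width 0.15 s, flanked by
  0.6× excitation lobes at ±0.35 s — the near-complete classic pause);
  SPN-like trains are homogeneous Poisson.
* Synaptic trials: alpha-shaped responses around a −60 mV resting
  potential (EPSP) or 0 pA holding (EPSC), log-normal per-cell amplitude
  dispersion (CV 0.2), paired pulses 100 ms apart with the second scaled
  by the PPR, multiplicative drug factor on the post condition.

Passing tests on these data therefore demonstrate correctness of the
estimators and detectors under the stated noise models — not robustness to
the artifacts of real recordings (electrode drift, movement, non-white
noise, bursty firing), which the generators deliberately omit.

## Problem sizes and defaults

The test suite and acceptance checks run at the following scales, chosen
to exercise each method at realistic operating points: sweep recordings at
10 kHz (electrical) or 2.5 kHz (optogenetic simulation); cable oracle at
N = 400 compartments, L = 5; 10 cells per noisy population; 300–400 s of
LFP at 1 kHz; 200 null simulations for the conditional-rate calibration;
10 seeds for Monte-Carlo power checks; 25-trial EPSP and 64-trial
paired-pulse blocks; 11 cells for the drug-effect emulation.

## Known limitations

* The quasi-linear description is local to one holding potential; mapping
  fitted (μ, τ) back to channel densities is not possible and is not
  attempted.
* Branched or tapering morphologies, active dendritic spikes, and ChR2
  desensitization are out of scope (unbranched homogeneous cable only).
* Phase-only fits identify parameters only up to the documented γ_R scale
  convention.
* The conditional-rate band is a pointwise null, not a simultaneous one;
  with ~100 central bins occasional single-bin excursions are expected by
  construction.
* Sleep staging, spike sorting, and the selection of recording sites are
  treated as given inputs and are not modelled.
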