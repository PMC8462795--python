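# Methods

## The generative model

Wakeful heart rate, averaged into 5-minute bins, is treated as a 24-h
cosinor plus a linear activity effect with stationary AR(1) residuals:

    HR_t = a − b·cos(π/12·(t − c)) + d·x_t + ε_t,        ε_{t+1} = k·ε_t + N(0, σ²)

* `a` — basal HR, bpm (prior box 30–120);
* `b` — circadian amplitude, bpm (0–20; `b = 0` means no rhythm);
* `c` — phase: clock hour of the daily HR minimum, circular on [0, 24);
* `d` — bpm per (steps/min) of concurrent activity (0–2);
* `σ` — innovation s.d. per 5-min bin, bpm (0.5–30);
* `k` — AR(1) carry-over per 5-min bin (0–0.999), representing hour-scale
  hormone-driven HR excursions (posture, meals, stress).

Averaging into bins keeps oversampled stretches from dominating; missing
HR is represented explicitly and never imputed. Binning apportions step
records across bin boundaries pro-rata by overlap of their native
recording interval, so step totals are conserved exactly.

The likelihood is the exact Gaussian density of the residuals at the
observed bins only: the first residual uses the stationary marginal
N(0, σ²/(1−k²)) (windows start mid-process), and a residual observed `g`
bins after its predecessor is conditionally
N(k^g·r_prev, σ²(1−k^{2g})/(1−k²)). The AR(1) Markov property makes this
exact for arbitrary gap patterns, which is why device-charging gaps do not
bias the fit. A dense multivariate-normal evaluation with covariance
σ²k^{|i−j|}/(1−k²) serves as the test oracle (agreement to 1e−8).

### The carry-over timescale

The cohort-central per-minute residual correlation is 0.9339. The package
defines `k` per 5-min bin throughout; the generator's central value is
therefore 0.9339⁵ ≈ 0.710. We considered the alternative reading (0.9339
per bin, e-folding ≈ 73 min): it makes the low-frequency noise so strong
that a 2-day window carries almost no phase information (Fisher s.d. of
`c` ≈ 5.6 h), which is incompatible with ±1 h tracked phase bands and
with day-scale re-entrainment dynamics that the method is known to
resolve. Under the per-minute reading the per-window phase s.d. is
≈ 1.5 h and tracked bands are ≈ ±1 h, consistent with those behaviours;
the residual e-folding time (≈ 15 min) is then the one aspect the
convention does not reconcile with an hour-scale narrative for the
correlated process. `decorrelation_time(k, bin_minutes) = −bin/ln k`
reports the e-folding time for any convention.

## Preprocessing

Sleep intervals from the device are consolidated: wake gaps shorter than
2 h inside sleep are absorbed (strict `<`), and the absorbed gap's data is
excluded from fitting. Wake "days" are spans between sleeps longer than
2 h (strict `>`; a 90-min nap excludes its own bins but does not split the
day). Each interior sleep with a bounded wake day on both sides defines
one 2-day fit window; observations are the awake bins with observed HR,
timed in hours since local midnight of the first day. Windows with fewer
than 48 five-minute bins (~4 h of data) are dropped — an added robustness
floor. Timestamps are civil local time; daylight-saving transitions pass
through unadjusted (documented caveat). Exports without sleep labels
(Apple-Watch style) fall back to treating HR gaps ≥ 4 h with zero steps as
sleep separators, emulating overnight charging.

## Inference

Goodman–Weare affine-invariant ensemble MCMC, stretch move with a = 2,
32 walkers, updated in two half-ensembles (each proposal uses only the
complementary, fixed half, preserving detailed balance while allowing
vectorised likelihood evaluation across walkers). Default budget 100,000
total samples per window; first 20% of sweeps discarded as burn-in.
Walkers start uniform in the prior box (phase from its prior). The sampler
is fully deterministic given a seed; a zero-acceptance window over 50
sweeps raises a diagnostic error. Correctness checks: closed-form moments
of a 6-d Gaussian, a χ² histogram test on a 1-d double well against
quadrature, and a moment comparison against emcee on a shared banana
target (emcee is only ever the cross-check).

`c` is summarised by the circular (resultant-vector) mean; 80% intervals
are central 10th–90th percentile intervals — quantile, not HPD, because
they are unique and match the banded-plot convention — taken circularly
about the mean for `c`. The effective-sample-size diagnostic is a Geyer
initial-positive-sequence estimate on walker-averaged traces.

Sequential tracking fits windows in time order; window n ≥ 2 receives a
wrapped-Gaussian phase prior centred on the previous window's circular
mean with s.d. 1 h. Only the phase is chained (phase continuity is the
scientifically asserted property; the other five parameters are refit
freely), and only the prior changes — with the chaining disabled the track
is bit-identical to independent fits. A failed window resets the chain to
the base prior. Phase difference is wrap(c − sleep-midpoint hour) in
(−12, 12], positive when the HR minimum trails the sleep midpoint. PACF of
phase-difference series uses Durbin–Levinson on sample autocorrelations
(statsmodels) with ±z₀.₉₇₅/√n bounds.

## Phase-response curve

Sign convention: phase shifts are advances when positive, so the nightly
response is y = wrap(c_prev − c_next) — an HR minimum arriving earlier the
next night is a positive shift. A free-running clock with intrinsic period
P drifts y = 24 − P per day (delay for P > 24).

For each day with phase estimates on both flanking nights (midpoints
16–32 h apart), activity between the midpoints is binned by relative hour
wrap(clock − c_prev) into 24 one-hour bins; every day contributes one
point to every bin (x may be zero — zero-activity points anchor the
intercepts). Attribution uses the previous night's posterior-mean phase;
propagating phase uncertainty into the PRC is out of scope. Per-bin simple
OLS (with intercept) gives the slope in h/step; bins with < 3 points or no
x-variance are missing. The 4-parameter curve m(h) = offset + A·s(h; φ, τ)
uses two half-cosines of lengths τ and 24 − τ (trough at φ; τ = 12 is the
symmetric cosine — the waveform family is our choice, the parameter count
is not). The fit is inverse-variance weighted by the slope standard
errors — otherwise near-empty bins at the sleep boundary, whose slopes are
numerically huge but carry no information, dominate — with multi-start
nonlinear least squares (grid plus ≥ 20 random restarts, τ bounded in
(1, 23), ties broken by RSS then τ).

Derived quantities: amplitude A; horizontal shift φ (non-identifiable and
flagged when A = 0); sinusoidality 1 − RSS(curve)/RSS(mean-only), clipped
to [0, 1] — a declared operationalization of curve "sinusoidality".

**Intrinsic period.** The period is 24 − δ₀ where δ₀ is the zero-activity
nightly drift (advance positive). With ≥ 36 days δ₀ is the intercept of
the day-level linear response y_d = δ₀ + Σ_h β_h·x_{d,h} — exactly the
shift a zero-activity day would show, and exact under the model that
defines the PRC (the per-bin slopes are this model's marginal
coefficients). Curve-mediated estimates (ȳ − Σ m(h)·x̄_h, or the intercept
of y on the curve-predicted effect, used as the short-series fallback)
carry the per-bin slope noise multiplied by the activity weights and are
several times noisier in simulation. A raw curve offset in h/step cannot
be a drift in h/day without weighting by an activity profile, so a "pure
offset" reading is not unit-consistent.

The non-overlap robustness variant recomputes responses from phase changes
between nights two apart (midpoints 40–56 h apart), whose two fits share
no data; its slope profile should nearly match the 24-h version. The
shuffled control permutes the day responses, which must flatten the curve.

## The synthetic-data generator

The generator is the package's ground-truth oracle. It emulates: 5-min HR
from the model exactly (stationary AR(1) with exact gap propagation),
sleep schedules with nightly jitter (s.d. 0.25 h), naps, shift-work
transitions, charging gaps, device sleep labels, and structured waking
activity — lognormal steps/min around 8/min (≈ 10k steps/day) with
commute peaks and stochastic exercise bouts spanning the 0–100+ steps/min
regime. Sleep-period HR, when emitted, is basal minus a fixed dip, purely
to exercise the exclusion logic. Cohort-central parameters: a = 73.5,
b = 4.0, c = 3.3, d = 0.32, σ = 6.9, k = 0.9339⁵.

The true clock updates once per simulated midnight:
c_{n+1} = wrap(c_n + (P − 24) − Σ_h prc(rel. hour)·steps_h). Phase is
piecewise constant within a day, matching the estimator's
one-phase-per-window granularity. The built-in sinusoidal PRC places its
advance peak at relative hour 5 (subjective morning); for a one-update
clock the stable entrained phase is then (activity centroid) − peak − 6,
putting a day-active schedule's HR minimum near 4 a.m. Entrainment
requires the feedback gain (amplitude × activity resultant × π/12) below
2; scenarios burn the clock in on a representative day's activity so
emitted data start at the entrained fixed point.

### Scenario design and what it does and does not show

* *Recovery/null scenarios* (`prc_recovery_config`, `prc_null_config`) use
  identification-clean activity: independent lognormal bins, dispersion
  0.3, no commute peaks or exercise bouts, and PRC amplitude 1.2e−4 h/step
  (max daily shift ≈ 0.5 h; gain ≈ 0.13 against the 0.2 h/day drift of a
  24.2-h clock). The per-bin simple regression that defines the PRC is
  unbiased only when activity is uncorrelated across relative-hour bins;
  with commute peaks and exercise bouts (features that migrate across bins
  as phase or schedule jitters) the slopes acquire an omitted-variable
  bias even with exact phases. Passing recovery tests therefore shows the
  *machinery* is correct, not that real-world activity structure cannot
  bias a simple-regression PRC — a caveat that applies to the method
  itself, not only to this implementation. PRC recovery tests also feed
  the estimator ground-truth nightly phases from the generator's ledger,
  isolating PRC estimation from phase-estimation noise, which would
  otherwise dominate the small per-step effects at desk-scale sample
  sizes (~100 days vs. the hundreds of days per subject the method is
  designed for).
* *Shift scenarios* (`shift_scenario_config`): a pinned clock through a
  7-h schedule shift (the phase track must stay flat), and a
  fast-entraining variant using a strong-rhythm subject (b = 8, σ = 5.5,
  inside the cohort ranges) whose tracked phase re-locks to the shifted
  schedule over 3–5 days. At cohort-central parameters the marginal
  per-window phase likelihood is too flat to follow day-scale clock
  swings; individuals differ, and the fast-adjuster behaviour belongs to
  strong-rhythm individuals.

The generator does not emulate: HR during sleep beyond a constant dip,
heart-rate variability or arrhythmia, nonlinear activity→HR response
(walking→running bends), light exposure, time-zone changes, or device
dropout other than contiguous gaps.

## Numerical choices and sizes

Simulation studies are sized to run on one CPU in minutes: recovery uses
20 independent 2-day fits at the full 100,000-sample budget plus 100
(tests) / 60 (acceptance script) reduced-budget (20,000-sample) fits for
interval calibration; tracking scenarios use 16–22 days at 20,000 samples
per window; PRC studies use 102 days. Tie-breaks and degenerate inputs:
overlapping sleep intervals merge with a warning; a sleep of exactly 2 h
does not split days and a wake gap of exactly 2 h is not absorbed;
constant series make the PACF undefined (error); `k = 1` or `σ = 0` yield
−∞ log-likelihood rather than exceptions so samplers can reject.

## Known limitations

* Phase precision at cohort-central parameters is ≈ ±1.5 h per isolated
  2-day window; sub-hour accuracy comes only from sequential tracking, and
  roughly half of independent window fits land within 1 h of truth. With
  no rhythm (b = 0) a single window's noise still induces an apparent
  amplitude of 2–3 bpm, so phase intervals narrow to ~8 h rather than
  spanning the full circle; unidentifiability shows instead as phase
  estimates scattering around the circle across replicates.
* The tracked phase is a prior-anchored random walk when the likelihood is
  weak: it can drift ~1–2 h over weeks even under a constant schedule.
* The PRC's per-bin simple regression inherits confounding from
  cross-bin activity covariance and from phase-dependent bin attribution
  at the wake/sleep edges (see scenario notes above).
* Daylight-saving and travel time-zone changes are not modelled; device
  local time is taken at face value.
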