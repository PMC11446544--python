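# Methods

This note documents the models, the synthetic-data generator, and the
numerical choices in `cardiorivalry`, in the order data flows through the
pipeline.

## ECG processing

**Containers.** `ECGRecord` holds one channel at a fixed sampling rate
(100 Hz is the default everywhere, matching consumer-grade bipolar
acquisition). `RPeakTrain` enforces strictly increasing peak times with
at least the 200 ms QRS refractory spacing. `CardiacEvents` pairs each
R-peak with its beat's T-wave offset (NaN where delineation failed) and
enforces `R_i < T_i < R_{i+1}`.

**Filters.** QRS enhancement uses an order-2 Butterworth bandpass at
5–15 Hz; baseline removal an order-2 Butterworth high-pass at 0.5 Hz.
Offline paths use zero-phase forward–backward filtering; the streaming
path uses the causal one-pass filter, because a real-time system cannot
look ahead.

**R-peak detection** is the Pan-Tompkins chain: bandpass, five-point
derivative, squaring, 150 ms moving-window integration, then adaptive
signal/noise thresholds (update coefficients 0.125/0.875), a 200 ms
refractory period, and a search-back rule triggered at 1.66× the running
mean of the last 8 R–R intervals (search-back acceptances update the
signal level with coefficient 0.25). Thresholds are initialised from the
first 2 s of the integrated signal, which makes detection invariant to
amplitude rescaling; no peaks are emitted during this learning period.
Accepted integration peaks are refined to the largest-magnitude
bandpassed sample in a 250 ms trailing window, then shifted back by the
bandpass filter's group delay at its 10 Hz centre (a known constant per
sampling rate). The decision logic consumes one sample at a time;
streaming and batch modes share it verbatim and therefore agree exactly,
which the tests assert. On 10-minute synthetic recordings at 100 Hz the
detector recovers >99% of beats within 50 ms (median error ~12 ms).

**T-wave offset delineation** is a deliberately simple surrogate for
wavelet-based delineators: on the 0.5 Hz high-passed signal, smoothed
with a zero-phase Gaussian of σ = 15 ms (the T-wave is slow; this
suppresses broadband noise without moving the crossing materially), the
T extremum is located in the window (R + 150 ms, R + 60% of the R–R
interval); the offset is the first sample after the extremum below 10%
of the T amplitude. Amplitude is measured from the post-T baseline — the
10th percentile of the signal between the T peak and 100 ms before the
next R — because high-pass filtering shifts the isoelectric line and an
absolute-zero threshold would fire early. Beats with an empty window or
no crossing are marked missing, as is the final beat. Against generator
ground truth the mean absolute error is ≤ 30 ms for noise up to ~7% of
the T amplitude; accuracy is not claimed to match any published
delineation package.

## Pulse scheduling

`SchedulerConfig` defaults: ADC latency 35 ms, target display peak
210 ms post-R (commanded at 175 ms so the on-screen peak lands at
210 ms), pulse scale 1/16 s (Gaussian SD), 100 Hz update grid, 60 Hz
render grid. The anti-phase pulse for beat *i* trails the in-phase pulse
by half of the R–R interval ending at beat *i*; the first beat has no
preceding interval and emits no anti-phase pulse. Overlapping pulses sum
additively (no combination rule is physically singled out; addition
keeps the trace linear in the peak train). Amplitude traces evaluate
each Gaussian only within ±6σ (truncation error < 2×10⁻⁸) and the render
trace is sample-and-hold of the most recent update-grid value, as a
frame-locked display would behave. Commanded and display-truth times are
both retained so that offline angle analyses use what the observer
actually saw.

## Cardiac angles and circular inference

An event at time t in beat i maps to

- systole (t < T_i):  angle = −π + π·(t − R_i)/(T_i − R_i)
- diastole (t ≥ T_i): angle = π·(t − T_i)/(R_{i+1} − T_i)

i.e. the R-peak sits at ±π, the T-offset at 0, each half linearly
interpolated. An event exactly at the R-peak returns −π (start of
systole; the same point as +π on the circle). Events in beats without a
T-offset, or outside the detected span, are dropped and counted.

Circular means are resultant-vector angles; a numerically zero resultant
raises rather than returning an arbitrary direction. Bootstrap CIs
(default 10,000 replicates) take the 2.5/97.5 percentiles of replicate
deviations from the point estimate after wrapping deviations to
(−π, π], which avoids wrap-around artifacts for means near ±π; bounds
may therefore exceed (−π, π] to describe a contiguous arc. The group
bootstrap resamples subjects with replacement and, within each chosen
subject, their events — capturing population and within-subject sampling
variability. Subjects are canonically ordered (by their angle arrays)
before per-subject random substreams are spawned from the root seed, so
results are invariant to input ordering at a fixed seed.

The manipulation check passes only if every subject's mean in-phase
angle is negative (systole) and mean anti-phase angle positive
(diastole). On closed-loop synthetic cohorts (detection → scheduling →
delineation → angles) in-phase means sit near −1.4 rad and anti-phase
means near +1.7 rad: with the template's 370 ms systole and a 210 ms
display peak, the exact in-phase angle is −π + π·(0.21/0.37) ≈ −1.36,
shifted slightly by the delineator's small late bias. The diastolic
angle depends on heart rate through the half-R–R delay.

## Dominance-duration statistics

Censored rows (intervals truncated at a block boundary) are excluded
from every analysis by default.

- **Paired estimation**: subject × condition arithmetic means (optionally
  stratified by eye); the paired systole-minus-diastole difference gets a
  bias-corrected accelerated bootstrap CI (scipy, 10,000 resamples of
  subjects); percentile CIs are available by option. A zero-spread
  difference vector short-circuits to a width-zero CI.
- **Gamma GEE**: trial-level durations, gamma family with log link,
  linear predictor = intercept + β·1[systole], clusters = subjects,
  exchangeable working correlation (independence available), robust
  sandwich covariance (statsmodels). The log link makes
  (exp(β) − 1)·100 the percent change in mean dominance duration, which
  is how the coefficient should be read. Wald z, two-sided normal p, and
  Wald 95% CIs are reported.
- **Power**: paired t-test power from the noncentral t distribution
  (df = n − 1, noncentrality d·√n); at d = 0.38 this gives 0.81 for
  n = 58 and 0.78 for n = 54 pairs.

Calibration, measured by simulation at the default cohort design
(54 subjects, two 10-min blocks, subject SD 0.3): the 95% Wald CI covers
the generative effect in ~92% of cohorts, and the nominal-5% Wald test
rejects ~9–10% of null cohorts. Both reflect the known small-sample
behaviour of cluster-robust Wald inference at ~50 clusters — here
aggravated because block tiling makes a subject's interval count depend
on their speed, so cluster variances are heterogeneous — not an
implementation defect: a one-sample t-test on the same per-subject
log-contrasts rejects ~6–7%, and the sandwich SE averages ~13% below the
empirical sampling SD under tiling while matching it exactly for iid
per-condition draws. Users wanting stricter null calibration at this
design scale should prefer the paired bootstrap.

## Discrimination mixture model

Subject i's correct count is modelled as
π·Binomial(k; n, ½ + B/2 marginalised over B ~ Beta(α, β)) +
(1 − π)·Binomial(k; n, ½), with priors α ~ Exponential(rate 1),
β ~ Exponential(rate ½) (mildly favouring accuracies near ½) and
π ~ Uniform(0, 1). The above-chance component is a *shifted*-Beta
Binomial spanning [½, 1], not a standard Beta-Binomial.

**Likelihood evaluation.** The marginal P(k | above-chance) has a
polynomial integrand in B, so it is computed exactly as a finite sum of
Beta functions in log space (log-sum-exp of positive terms); this is
stable for any α, β > 0, including endpoint-singular shapes α < 1 or
β < 1, and is verified against adaptive quadrature and a 10⁶-draw
Monte-Carlo oracle.

**Sampling.** The likelihood is marginalised over the per-subject labels
(no discrete latents). The default backend evaluates the joint posterior
on a regular grid — 120 prevalence cells on (0, 1), 60 α cells on
(0, 10], 60 β cells on (0, 20]; truncated prior mass beyond those ranges
is < 5×10⁻⁵ — then draws weighted samples with uniform within-cell
jitter. It is deterministic for a fixed seed, which the tests rely on.
An emcee ensemble sampler over (logit π, log α, log β) is available as
`backend="mcmc"`, reporting a split-chain R-hat (flagged if ≥ 1.01); the
two backends agree on posterior means. HDIs are shortest intervals
containing 95% of draws.

**Membership and screening.** P(above-chance | k) is the posterior
average of the Bayes ratio π·L(k)/[π·L(k) + (1 − π)·Binomial(k; n, ½)];
for a degenerate posterior this reduces exactly to the single-draw
closed form. The screen retains subjects with membership ≤ 0.05 and
reports the largest retained accuracy as the effective cutoff, alongside
the one-sided exact binomial flag (p = P(X ≥ k | n, ½)) so the two
criteria can be compared.

**Identifiability.** With ~54 subjects the posterior is broad: a
likelihood ridge trades high prevalence against α → 0 (the above-chance
accuracy law collapsing onto chance), so prevalence HDIs are wide and
membership probabilities of genuinely at-chance subjects can sit well
above 0.05 — on default synthetic cohorts the 0.05 screen often retains
nobody. Simulation-based calibration (parameters drawn from the priors)
shows uniform posterior ranks, i.e. the posterior itself is correctly
computed; at a fixed boundary-adjacent truth (prevalence 0.10) the 95%
HDI covers in ~85–90% of cohorts, the usual gap between Bayesian
credible and frequentist coverage under weak identification.

## Synthetic-data generator

What it emulates, and the defaults (all configurable in `CohortConfig`):

- **R–R series**: AR(1) Gaussian intervals (coefficient 0.3), stationary
  mean 0.8 s per subject (population SD 0.07 s), beat-to-beat SD 0.05 s,
  floored at 0.3 s — autocorrelated sinus variability in the 60–100 bpm
  range, no arrhythmia.
- **ECG**: per beat a unit Gaussian QRS (σ = 15 ms) and a Gaussian
  T-wave (amplitude 0.3, σ = 60 ms, centred 250 ms post-R) plus white
  noise; the ground-truth T-offset is centre + 2σ = 370 ms post-R,
  recorded exactly. Single-lead, upright polarity, fixed morphology — it
  exercises detection and delineation logic but does not represent
  morphological variability, electrode artifacts, or rate-dependent QT
  shortening (the T timing is fixed, not a fraction of R–R).
- **Rivalry sessions**: two 10-min blocks of alternating dominance
  intervals; durations gamma with shape 4 and mean
  2.5 s · exp(subject effect) · (1 + 0.0264·1[systole]); subject effects
  log-normal with SD 0.3; the eye↔condition mapping swaps between blocks;
  the final interval of each block is truncated and flagged `censored`.
  Shape 4 / mean 2.5 s are conventional rivalry values, chosen once; no
  mixed or piecemeal percepts are modelled.
- **Discrimination**: 120 trials per subject; above-chance with
  probability 0.10, accuracy ½ + Beta(2, 4)/2, latent labels returned as
  ground truth.

Passing tests on these cohorts show the *pipeline* recovers what the
generator encodes under the stated laws; they cannot certify behaviour
on real ECG morphology or real rivalry dynamics beyond those laws.

## Problem sizes in tests and the acceptance script

The calibration tests simulate 200 effect cohorts and 400 null cohorts
for the GEE and 100 cohorts for the mixture, all at the full 54-subject
design; the closed-loop manipulation check uses 20 subjects × 10 min of
ECG at 100 Hz with 10,000 bootstrap replicates. The acceptance script
analyses one default 54-subject cohort per stage and a 20-subject
closed-loop cohort, with 10,000 draws/replicates for posterior and
bootstrap summaries — sizes chosen to match the study design while
keeping a full run in the order of a minute.

## Known limitations

- The T-offset delineator is a threshold rule with a stated error
  budget, not a wavelet delineator; its small (~15–20 ms) late bias is
  visible in closed-loop angle summaries.
- No handling of ectopic beats or detection dropouts beyond scheduling
  from whatever train the detector emits.
- The GEE Wald test over-rejects at this cluster count (see above).
- Mixture prevalence is weakly identified at n ≈ 54; conclusions about
  the *screen* on synthetic cohorts should use the membership
  probabilities, not the retained fraction, as the quantity of interest.
- Survival-style treatment of censored intervals, GLMMs, and von Mises
  parametric circular inference are out of scope.
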