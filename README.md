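# cardiorivalry

Analysis pipeline for cardiac–visual binocular-rivalry experiments: does
entraining a visual stimulus to cardiac systole change how long that
stimulus dominates perception?

The package covers every computational stage of such a study, end to end:

1. **Real-time-style ECG processing** — 5–15 Hz bandpass, streaming
   Pan-Tompkins R-peak detection (sample-by-sample, causal, with a
   vectorised batch mode that is exactly equivalent), and offline T-wave
   offset delineation.
2. **Cardiac-phase-locked stimulus scheduling** — Gaussian "pulses"
   commanded 175 ms after each R-peak so that, after the amplifier's
   35 ms analog-to-digital latency, they peak on screen at 210 ms post-R
   (peak systolic pressure); an anti-phase pulse trails by half the
   preceding R–R interval, landing in diastole.
3. **Cardiac angles** — event times mapped to a phase angle with the
   R-peak at ±π and the T-wave offset at 0, so systole is the negative
   half-circle and diastole the positive half; subject-level and
   hierarchical (random-effects) circular bootstraps implement the
   manipulation check.
4. **Dominance-duration statistics** — subject-wise paired estimation
   with a 10,000-replicate BCa bootstrap, a trial-level gamma GEE
   (log link, systole dummy, exchangeable working correlation over
   subject clusters, robust SEs), and paired-t power via the noncentral
   t distribution.
5. **Heartbeat-discrimination mixture model** — each subject's correct
   count k of n trials is either at-chance, k ~ Binomial(n, ½), or
   above-chance with accuracy p = ½ + B/2, B ~ Beta(α, β); priors
   α ~ Exp(1), β ~ Exp(½), prevalence π ~ Uniform(0, 1). Posterior
   membership by Bayes' rule and an at-chance screen at 95% posterior
   probability.
6. **Synthetic cohorts** — generators for R–R series, template ECG with
   exact ground-truth fiducials, gamma-distributed rivalry sessions with
   a multiplicative systolic effect, and mixture-drawn discrimination
   outcomes, so the whole pipeline is testable without any recorded data.

## Worked example

```python
import cardiorivalry as cr

cfg = cr.CohortConfig()                       # 54 subjects, 2 x 10-min blocks
table = cr.simulate_rivalry_cohort(cfg, seed=11)

est = cr.paired_bootstrap(table, n_boot=10_000, seed=0)
res = cr.fit_gamma_gee(table)
```

Running `python examples/05_dominance_analysis.py` (which does exactly
this) prints:

```
paired difference (systole - diastole): 0.046 s (95% CI [-0.000, 0.087])
gamma GEE systole coefficient: beta = 0.0176 (95% CI [0.0043, 0.0309]), z = 2.59, p = 0.0095
interpreted effect: 1.78% longer dominance (95% CI [0.43, 3.14]) for systole-entrained stimuli

power at d = 0.38: n=58 -> 0.81, n=54 -> 0.78
```

The GEE coefficient lives on the log scale, so `exp(beta) − 1` is the
percent change in mean dominance duration attributable to systolic
entrainment; the paired difference is the same effect expressed in
seconds at the subject level. This simulated cohort was generated with a
2.64% multiplicative effect, and the fitted CI covers it.

The other scripts in `examples/` each demonstrate one capability
(cohort generation and BIDS-style I/O, R-peak detection, pulse
scheduling, the closed-loop manipulation check, the discrimination
mixture, and a runner for re-analysing a deposited dataset).

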