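"""Dominance-duration analysis of a rivalry cohort.

Simulates the default 54-subject cohort with a ~2.64% systolic
entrainment effect, then runs the two inferential analyses: the
subject-level paired bootstrap and the trial-level gamma GEE.
"""

import cardiorivalry as cr

cfg = cr.CohortConfig()  # 54 subjects, 2 x 10-min blocks
table = cr.simulate_rivalry_cohort(cfg, seed=11)

est = cr.paired_bootstrap(table, n_boot=10_000, seed=0)
print(
    f"paired difference (systole - diastole): {est.mean_diff:.3f} s "
    f"(95% CI [{est.ci_low:.3f}, {est.ci_high:.3f}])"
)

res = cr.fit_gamma_gee(table)
print(
    f"gamma GEE systole coefficient: beta = {res.beta:.4f} "
    f"(95% CI [{res.ci_low:.4f}, {res.ci_high:.4f}]), "
    f"z = {res.z:.2f}, p = {res.p:.4f}"
)
lo, hi = res.pct_ci
print(f"interpreted effect: {res.pct_change:.2f}% longer dominance "
      f"(95% CI [{lo:.2f}, {hi:.2f}]) for systole-entrained stimuli")

print(f"\npower at d = 0.38: n=58 -> {cr.paired_t_power(0.38, 58):.2f}, "
      f"n=54 -> {cr.paired_t_power(0.38, 54):.2f}")
# beta on the log scale is the multiplicative effect of systolic
# entrainment; exp(beta) - 1 converts it to a percent change in mean
# dominance duration.
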