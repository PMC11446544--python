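"""Rerun the full analysis on a deposited BIDS-style dataset.

Point ``DATA_ROOT`` at a local copy of the archived study data (one
``sub-XX/`` directory per subject with an ECG recording, rivalry events,
and discrimination trials; see cardiorivalry.io for the expected files).
The same pipeline runs unchanged on synthetic cohorts — see the other
examples — so this script only wires the on-disk layout to the analyses.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import cardiorivalry as cr
from cardiorivalry import io
from cardiorivalry.phase import cardiac_angle, group_bootstrap

DATA_ROOT = Path(sys.argv[1]) if len(sys.argv) > 1 else Path("data/ecg-rivalry")

if not DATA_ROOT.exists():
    sys.exit(
        f"{DATA_ROOT} not found: download the archived dataset and pass its "
        "path as the first argument"
    )

rivalry_frames, discrim_rows, angles_in, angles_anti = [], [], [], []
for sub in sorted(DATA_ROOT.glob("sub-*")):
    events = io.read_events(sub / "task-rivalry_events.tsv")
    events["subject"] = sub.name
    rivalry_frames.append(events)
    d = io.read_events(sub / "task-discrim_events.tsv")
    discrim_rows.append(
        dict(subject=sub.name, k=int(d["correct"].sum()), n=len(d))
    )
    ecg_path = sub / "ecg.tsv.gz"
    if ecg_path.exists():
        record = io.read_ecg(ecg_path)
        sched = cr.replay_session(record)
        rpeaks = cr.detect_rpeaks(record)
        ev = cr.detect_t_offsets(record, rpeaks)
        lo, hi = ev.r_times[0], ev.r_times[-1]
        inp, ant = sched.inphase_peaks, sched.antiphase_peaks
        angles_in.append(cardiac_angle(inp[(inp > lo) & (inp < hi)], ev)[0])
        angles_anti.append(cardiac_angle(ant[(ant > lo) & (ant < hi)], ev)[0])

table = pd.concat(rivalry_frames, ignore_index=True)
est = cr.paired_bootstrap(table, n_boot=10_000, seed=0)
res = cr.fit_gamma_gee(table)
print(f"paired difference: {est.mean_diff:.3f} s "
      f"[{est.ci_low:.3f}, {est.ci_high:.3f}]")
print(f"gamma GEE: beta = {res.beta:.3f} [{res.ci_low:.3f}, {res.ci_high:.3f}], "
      f"z = {res.z:.3f}, p = {res.p:.3f} ({res.pct_change:.2f}% change)")

disc = pd.DataFrame(discrim_rows)
post = cr.fit_mixture(disc, n_draws=10_000, seed=0)
s = post.summary()
print(f"prevalence: {100 * s['prevalence_mean']:.2f}% "
      f"[{100 * s['prevalence_hdi_low']:.2f}, {100 * s['prevalence_hdi_high']:.2f}]; "
      f"above-chance accuracy {s['accuracy_mean']:.3f}")
kept, cutoff = cr.screen_at_chance(disc, post, threshold=0.05)
print(f"retained at 0.05 screen: {100 * len(kept) / len(disc):.1f}% "
      f"(cutoff {cutoff:.3f})")
flags = [cr.binomial_above_chance(r.k, r.n)[1] for r in disc.itertuples()]
print(f"binomially above chance: {100 * np.mean(flags):.2f}%")

if angles_in:
    g_in = group_bootstrap(angles_in, n_boot=10_000, seed=0)
    g_anti = group_bootstrap(angles_anti, n_boot=10_000, seed=1)
    print(f"group cardiac angles: in-phase {g_in.mean_angle:.2f} rad "
          f"[{g_in.ci_low:.2f}, {g_in.ci_high:.2f}], "
          f"anti-phase {g_anti.mean_angle:.2f} rad "
          f"[{g_anti.ci_low:.2f}, {g_anti.ci_high:.2f}]")

# then rerun the GEE on confidently at-chance subjects only
at_chance = table[table["subject"].isin(set(kept))]
if at_chance["subject"].nunique() >= 2:
    res2 = cr.fit_gamma_gee(at_chance)
    print(f"GEE, at-chance subjects only: beta = {res2.beta:.3f} "
          f"[{res2.ci_low:.3f}, {res2.ci_high:.3f}], z = {res2.z:.3f}, "
          f"p = {res2.p:.3f}")
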