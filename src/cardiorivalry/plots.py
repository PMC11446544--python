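"""Estimation-statistics plots for the rivalry analysis."""

from __future__ import annotations

import numpy as np

from .rivalry import PairedEstimate


def paired_estimation_plot(estimate: PairedEstimate, ax_pair=None, ax_boot=None):
    """Paired-slopes panel above a bootstrap-distribution panel.

    Top: each subject's systole and diastole mean dominance durations
    joined by a line.  Bottom: the bootstrap distribution of the mean
    paired difference with its 95% CI.  Returns the two axes.
    """
    import matplotlib.pyplot as plt

    if ax_pair is None or ax_boot is None:
        _, (ax_pair, ax_boot) = plt.subplots(
            2, 1, figsize=(4, 6), height_ratios=[2, 1], sharex=False
        )
    wide = estimate.per_subject_means.pivot(
        index="subject", columns="condition", values="mean_duration"
    )
    for _, row in wide.iterrows():
        ax_pair.plot([0, 1], [row["diastole"], row["systole"]], alpha=0.4, lw=1)
    ax_pair.set_xticks([0, 1], ["diastole", "systole"])
    ax_pair.set_ylabel("mean dominance duration (s)")

    diffs = (wide["systole"] - wide["diastole"]).to_numpy()
    rng = np.random.default_rng(0)
    reps = np.array(
        [
            diffs[rng.integers(0, diffs.size, diffs.size)].mean()
            for _ in range(2000)
        ]
    )
    ax_boot.hist(reps, bins=40, density=True, alpha=0.6)
    ax_boot.axvline(estimate.mean_diff, color="k")
    ax_boot.axvline(estimate.ci_low, color="k", ls="--")
    ax_boot.axvline(estimate.ci_high, color="k", ls="--")
    ax_boot.set_xlabel("paired difference, systole - diastole (s)")
    ax_boot.set_ylabel("bootstrap density")
    return ax_pair, ax_boot
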