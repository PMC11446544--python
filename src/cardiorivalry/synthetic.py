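"""Synthetic cohorts with the statistical structure the analyses assume.

Every downstream stage of the pipeline (R-peak detection, pulse
scheduling, cardiac-angle checks, the gamma GEE, the discrimination
mixture model) can be exercised on data from this module alone.

The generators emulate:

* per-subject sinus rhythm as an AR(1) R-R interval series (~60-100 bpm
  with beat-to-beat variability),
* single-channel ECG built from a Gaussian beat template (narrow QRS,
  broad low-amplitude T-wave) with exact ground-truth fiducials,
* two 10-min rivalry blocks of alternating gamma-distributed dominance
  intervals with a multiplicative systole-entrainment effect and
  log-normal subject heterogeneity, and
* 120-trial heartbeat-discrimination outcomes from a two-component
  population: at-chance responders (Binomial at p = 0.5) and above-chance
  perceivers whose accuracy is 0.5 + B/2 with B ~ Beta(alpha, beta).

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg import CardiacEvents, ECGRecord, RPeakTrain

__all__ = [
    "CohortConfig",
    "simulate_rr_series",
    "simulate_ecg",
    "simulate_rivalry_session",
    "simulate_rivalry_cohort",
    "simulate_discrimination",
]

#: Hard floor on a single R-R interval (s): shortest plausible sinus beat.
RR_FLOOR = 0.3
#: AR(1) coefficient of successive R-R intervals.
RR_AR1 = 0.3
#: QRS template width (s).
QRS_SIGMA = 0.015
#: T-wave template width (s) and centre relative to the R-peak (s).
T_SIGMA = 0.06
T_CENTER = 0.25
#: T-wave amplitude relative to the (unit) QRS amplitude.
T_AMPLITUDE = 0.3


@dataclass
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    Defaults mirror the study conditions: 54 subjects, two 10-min rivalry
    blocks, 120 discrimination trials, a ~2.6% multiplicative systolic
    effect on mean dominance duration, and a discrimination population in
    which ~10% of subjects perceive their heartbeat above chance with
    accuracy 0.5 + Beta(2, 4)/2.
    """

    n_subjects: int = 54
    n_blocks: int = 2
    block_duration: float = 600.0
    mean_rr: float = 0.8          # population mean of subject mean R-R (s)
    mean_rr_sd: float = 0.07      # between-subject SD of mean R-R (s)
    rr_sd: float = 0.05           # within-subject beat-to-beat SD (s)
    gamma_shape: float = 4.0      # dominance-duration gamma shape
    mean_dominance: float = 2.5   # baseline mean dominance duration (s)
    systole_effect: float = 0.0264  # multiplicative effect on the mean
    subject_sd: float = 0.3       # log-scale SD of the subject random effect
    n_discrim_trials: int = 120
    prevalence: float = 0.10      # proportion of above-chance perceivers
    alpha: float = 2.0            # above-chance accuracy law: B ~ Beta(alpha, beta)
    beta: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.block_duration, self.mean_rr, self.mean_dominance) <= 0:
            raise ValueError("all durations must be positive")
        if not 0 <= self.prevalence <= 1:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.gamma_shape <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("shape parameters must be positive")
        if self.systole_effect <= -1:
            raise ValueError("systole_effect must exceed -1")
        if self.n_subjects < 1 or self.n_blocks < 1 or self.n_discrim_trials < 1:
            raise ValueError("counts must be positive")


def _subject_rng(seed: int, subject: int) -> np.random.Generator:
    """Independent substream per subject, invariant to iteration order."""
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(subject + 1)[-1])


def simulate_rr_series(
    mean_rr: float, rr_sd: float, duration: float, seed: int
) -> RPeakTrain:
    """AR(1) Gaussian R-R intervals, cumulated into an R-peak train.

    Intervals have stationary mean ``mean_rr`` and SD ``rr_sd`` with a
    nonnegative first-order autocorrelation (coefficient 0.3), floored at
    0.3 s.  The train starts at t = 0 and covers ``[0, duration]``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if rr_sd < 0 or (rr_sd > 0 and mean_rr <= 3 * rr_sd):
        raise ValueError("require mean_rr > 3 * rr_sd >= 0")
    rng = np.random.default_rng(seed)
    n_max = int(np.ceil(duration / max(RR_FLOOR, mean_rr - 5 * rr_sd))) + 2
    if rr_sd == 0:
        rr = np.full(n_max, mean_rr)
    else:
        eps_sd = rr_sd * np.sqrt(1.0 - RR_AR1**2)
        dev = np.empty(n_max)
        dev[0] = rng.normal(0.0, rr_sd)
        shocks = rng.normal(0.0, eps_sd, n_max - 1)
        for i in range(1, n_max):
            dev[i] = RR_AR1 * dev[i - 1] + shocks[i - 1]
        rr = np.maximum(mean_rr + dev, RR_FLOOR)
    times = np.concatenate([[0.0], np.cumsum(rr)])
    times = times[times <= duration + 1e-9]
    return RPeakTrain(times, fs=np.nan)


def simulate_ecg(
    rpeaks: RPeakTrain, fs: float = 100.0, noise_sd: float = 0.0, seed: int = 0
) -> tuple[ECGRecord, CardiacEvents]:
    """Template ECG with exact ground-truth fiducials.

    Each beat is a unit-amplitude Gaussian QRS (sigma 15 ms) at the R time
    plus a broader T-wave (amplitude 0.3, sigma 60 ms, centred 250 ms
    post-R); white Gaussian noise of SD ``noise_sd`` is added.  The
    ground-truth T-offset of each beat is the T centre + 2 sigma (370 ms
    post-R); beats whose true offset would not fall strictly before the
    next R-peak, and the final beat, carry NaN.
    """
    if fs < 50:
        raise ValueError("sampling rate below 50 Hz cannot resolve the QRS")
    r = np.asarray(rpeaks.times, dtype=float)
    if r.size == 0:
        raise ValueError("need at least one R-peak")
    duration = r[-1] + 1.0
    t = np.arange(0.0, duration, 1.0 / fs)
    x = np.zeros_like(t)

    def _add(center: float, sigma: float, amp: float) -> None:
        lo = max(0, int(np.ceil((center - 6 * sigma) * fs)))
        hi = min(t.size, int(np.floor((center + 6 * sigma) * fs)) + 1)
        if hi > lo:
            x[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / sigma) ** 2)

    for rt in r:
        _add(rt, QRS_SIGMA, 1.0)
        _add(rt + T_CENTER, T_SIGMA, T_AMPLITUDE)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, x.size)
    t_off = np.full(r.size, np.nan)
    truth = r + T_CENTER + 2 * T_SIGMA
    ok = truth[:-1] < r[1:]
    t_off[:-1][ok] = truth[:-1][ok]
    return ECGRecord(x, fs), CardiacEvents(r, t_off)


def _session_frame(
    cfg: CohortConfig, subject_effect: float, rng: np.random.Generator, subject: int
) -> pd.DataFrame:
    rows = []
    base_mean = cfg.mean_dominance * np.exp(subject_effect)
    for block in range(1, cfg.n_blocks + 1):
        # counterbalancing: eye <-> condition mapping swaps between blocks
        systole_eye = "left" if (block % 2 == 1) else "right"
        first = int(rng.integers(2))  # which condition dominates first
        # draw alternating-condition gamma intervals in chunks until they
        # tile the block, then truncate the final one at the boundary
        durations = np.empty(0)
        is_sys = np.empty(0, dtype=bool)
        while durations.sum() < cfg.block_duration:
            m = max(16, int(1.5 * cfg.block_duration / base_mean))
            idx = np.arange(is_sys.size, is_sys.size + m)
            sys_chunk = (idx + first) % 2 == 0
            means = base_mean * np.where(sys_chunk, 1.0 + cfg.systole_effect, 1.0)
            chunk = rng.gamma(cfg.gamma_shape, means / cfg.gamma_shape)
            durations = np.concatenate([durations, chunk])
            is_sys = np.concatenate([is_sys, sys_chunk])
        stop = int(np.searchsorted(np.cumsum(durations), cfg.block_duration))
        durations, is_sys = durations[: stop + 1], is_sys[: stop + 1]
        durations[-1] -= durations.sum() - cfg.block_duration
        onset = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        other_eye = "right" if systole_eye == "left" else "left"
        rows.append(
            pd.DataFrame(
                dict(
                    subject=subject,
                    block=block,
                    onset=onset,
                    duration=durations,
                    eye=np.where(is_sys, systole_eye, other_eye),
                    condition=np.where(is_sys, "systole", "diastole"),
                    censored=np.arange(durations.size) == durations.size - 1,
                )
            )
        )
    return pd.concat(rows, ignore_index=True)


def simulate_rivalry_session(
    cfg: CohortConfig, subject_effect: float, seed: int, subject: int = 0
) -> pd.DataFrame:
    """One subject's rivalry session as a dominance table.

    Alternating systole/diastole dominance intervals tile each block;
    durations follow a gamma law with shape ``cfg.gamma_shape`` and mean
    ``mean_dominance * exp(subject_effect) * (1 + systole_effect)`` for the
    systole condition (no multiplier in diastole).  The final interval of
    each block is truncated at the block boundary and flagged ``censored``.
    The eye carrying the systole stimulus swaps between blocks.
    """
    return _session_frame(cfg, subject_effect, np.random.default_rng(seed), subject)


def simulate_rivalry_cohort(cfg: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Full cohort: per-subject log-normal random effects, one session each."""
    seed = cfg.seed if seed is None else seed
    frames = []
    for s in range(cfg.n_subjects):
        rng = _subject_rng(seed, s)
        eff = rng.normal(0.0, cfg.subject_sd)
        frames.append(_session_frame(cfg, eff, rng, subject=s))
    return pd.concat(frames, ignore_index=True)


def simulate_discrimination(cfg: CohortConfig, seed: int | None = None) -> pd.DataFrame:
    """Heartbeat-discrimination outcomes for a cohort.

    Each subject is an above-chance perceiver with probability
    ``cfg.prevalence``; at-chance subjects score Binomial(n, 0.5) correct,
    above-chance subjects draw accuracy p = 0.5 + B/2, B ~ Beta(alpha,
    beta), then score Binomial(n, p).  The latent label and latent accuracy
    are returned as ground truth.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = cfg.n_discrim_trials
    above = rng.random(cfg.n_subjects) < cfg.prevalence
    p = np.full(cfg.n_subjects, 0.5)
    p[above] = 0.5 + 0.5 * rng.beta(cfg.alpha, cfg.beta, int(above.sum()))
    k = rng.binomial(n, p)
    return pd.DataFrame(
        dict(
            subject=np.arange(cfg.n_subjects), k=k, n=n,
            above_chance=above, latent_accuracy=p,
        )
    )
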