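"""Reading and writing the BIDS-style layout used by the pipeline.

One directory per subject (``sub-01/`` ...) holding:

* ``ecg.tsv`` or ``ecg.tsv.gz`` — single column ``value`` (one ECG sample
  per row) with a JSON sidecar ``ecg.json`` carrying ``SamplingFrequency``
  and ``StartTime``,
* ``task-rivalry_events.tsv`` — onset, duration, eye, condition, block,
  censored,
* ``task-discrim_events.tsv`` — trial, correct.

All times are seconds relative to the recording start.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ecg import CardiacEvents, ECGRecord, RPeakTrain
from .synthetic import (
    CohortConfig,
    simulate_discrimination,
    simulate_ecg,
    simulate_rivalry_cohort,
    simulate_rr_series,
    _subject_rng,
)

__all__ = [
    "write_ecg",
    "read_ecg",
    "write_events",
    "read_events",
    "write_rpeaks",
    "read_rpeaks",
    "write_cardiac_events",
    "read_cardiac_events",
    "write_cohort",
    "read_config",
    "write_config",
]


def write_ecg(path: Path | str, record: ECGRecord) -> None:
    path = Path(path)
    pd.DataFrame({"value": record.samples}).to_csv(path, sep="\t", index=False)
    sidecar = path.with_name(path.name.split(".")[0] + ".json")
    sidecar.write_text(
        json.dumps(
            {"SamplingFrequency": record.fs, "StartTime": record.start_time}
        )
    )


def read_ecg(path: Path | str) -> ECGRecord:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    sidecar = path.with_name(path.name.split(".")[0] + ".json")
    meta = json.loads(sidecar.read_text())
    return ECGRecord(
        df["value"].to_numpy(), meta["SamplingFrequency"], meta.get("StartTime", 0.0)
    )


def write_events(path: Path | str, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path: Path | str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_rpeaks(path: Path | str, train: RPeakTrain) -> None:
    pd.DataFrame({"time_s": train.times}).to_csv(path, sep="\t", index=False)


def read_rpeaks(path: Path | str, fs: float = np.nan) -> RPeakTrain:
    return RPeakTrain(pd.read_csv(path, sep="\t")["time_s"].to_numpy(), fs)


def write_cardiac_events(path: Path | str, events: CardiacEvents) -> None:
    pd.DataFrame(
        {"r_time_s": events.r_times, "t_offset_s": events.t_offsets}
    ).to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_cardiac_events(path: Path | str) -> CardiacEvents:
    df = pd.read_csv(path, sep="\t", na_values="n/a")
    return CardiacEvents(df["r_time_s"].to_numpy(), df["t_offset_s"].to_numpy())


def write_pulse_schedule(path: Path | str, schedule) -> None:
    """Serialize pulse peaks as an events table (time_s, stimulus, kind)."""
    frames = [
        pd.DataFrame(
            {"time_s": schedule.inphase_peaks, "stimulus": "inphase",
             "kind": "display"}
        ),
        pd.DataFrame(
            {"time_s": schedule.commanded_inphase_peaks, "stimulus": "inphase",
             "kind": "commanded"}
        ),
        pd.DataFrame(
            {"time_s": schedule.antiphase_peaks, "stimulus": "antiphase",
             "kind": "display"}
        ),
    ]
    out = pd.concat(frames, ignore_index=True).sort_values("time_s")
    out.to_csv(path, sep="\t", index=False)


def write_config(path: Path | str, cfg: CohortConfig) -> None:
    Path(path).write_text(yaml.safe_dump(vars(cfg)))


def read_config(path: Path | str) -> CohortConfig:
    return CohortConfig(**yaml.safe_load(Path(path).read_text()))


def write_cohort(
    root: Path | str,
    cfg: CohortConfig,
    with_ecg: bool = True,
    ecg_noise_sd: float = 0.05,
) -> Path:
    """Write a full synthetic cohort as a BIDS-like tree.

    ``sub-XX/`` directories gain rivalry and discrimination event tables
    and (optionally) a template ECG recording spanning the rivalry blocks.
    Returns the root path.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    write_config(root / "cohort.yaml", cfg)
    rivalry = simulate_rivalry_cohort(cfg)
    discrim = simulate_discrimination(cfg)
    for s in range(cfg.n_subjects):
        sub = root / f"sub-{s + 1:02d}"
        sub.mkdir(exist_ok=True)
        write_events(
            sub / "task-rivalry_events.tsv",
            rivalry[rivalry["subject"] == s].drop(columns="subject"),
        )
        row = discrim[discrim["subject"] == s].iloc[0]
        trials = np.zeros(cfg.n_discrim_trials, dtype=int)
        trials[: int(row["k"])] = 1
        rng = _subject_rng(cfg.seed, s)
        rng.shuffle(trials)
        write_events(
            sub / "task-discrim_events.tsv",
            pd.DataFrame({"trial": np.arange(trials.size), "correct": trials}),
        )
        if with_ecg:
            mean_rr = float(
                np.clip(rng.normal(cfg.mean_rr, cfg.mean_rr_sd), 0.5, 1.2)
            )
            train = simulate_rr_series(
                mean_rr, cfg.rr_sd, cfg.n_blocks * cfg.block_duration,
                seed=int(rng.integers(2**31 - 1)),
            )
            record, truth = simulate_ecg(
                train, noise_sd=ecg_noise_sd, seed=int(rng.integers(2**31 - 1))
            )
            write_ecg(sub / "ecg.tsv.gz", record)
            write_cardiac_events(sub / "cardiac_events.tsv", truth)
    return root
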