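"""Cardiac-entrained pulse scheduling.

Turns a stream of detected R-peaks into the Gaussian "pulse" time courses
driving the two rival stimuli: the in-phase stimulus is commanded to peak
175 ms after each R-peak so that, after the amplifier's ~35 ms
analog-to-digital latency, it actually peaks on screen at 210 ms post-R
(peak systolic pressure); the anti-phase stimulus is delayed by half the
preceding R-R interval, landing in diastole on average.  Amplitude traces
are sampled on a 100 Hz update grid and resampled to the 60 Hz render
grid by sample-and-hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ecg import ECGRecord, RPeakTrain, detect_rpeaks

__all__ = [
    "SchedulerConfig",
    "PulseSchedule",
    "schedule_inphase",
    "schedule_antiphase",
    "render_pulse_trace",
    "replay_session",
]


@dataclass
class SchedulerConfig:
    """Timing constants of the stimulus scheduler.

    ``adc_latency`` is the known acquisition latency compensated by
    commanding pulses early; ``target_display_peak`` is where the in-phase
    pulse should truly peak on screen, relative to the R-peak;
    ``pulse_scale`` is the Gaussian SD of a pulse.
    """

    adc_latency: float = 0.035
    target_display_peak: float = 0.210
    pulse_scale: float = 1.0 / 16.0
    update_rate: float = 100.0
    render_rate: float = 60.0

    def __post_init__(self) -> None:
        if not self.target_display_peak > self.adc_latency >= 0:
            raise ValueError("need target_display_peak > adc_latency >= 0")
        if self.pulse_scale <= 0:
            raise ValueError("pulse_scale must be positive")
        if self.update_rate <= 0 or self.render_rate <= 0:
            raise ValueError("rates must be positive")


@dataclass
class PulseSchedule:
    """Commanded and display-truth pulse peaks plus sampled amplitude traces.

    ``inphase_peaks`` / ``antiphase_peaks`` are display-truth times; the
    commanded in-phase peaks lead the display-truth peaks by the
    analog-to-digital latency.  ``amplitude_trace`` holds per-stimulus
    amplitudes on the update grid, ``rendered_trace`` the sample-and-hold
    values on the render grid.
    """

    inphase_peaks: np.ndarray
    antiphase_peaks: np.ndarray
    commanded_inphase_peaks: np.ndarray
    update_times: np.ndarray = field(default=None)
    amplitude_trace: dict = field(default_factory=dict)
    render_times: np.ndarray = field(default=None)
    rendered_trace: dict = field(default_factory=dict)


def schedule_inphase(rpeaks: RPeakTrain, cfg: SchedulerConfig | None = None):
    """In-phase (systole) pulse peaks, one per R-peak.

    Returns ``(commanded, display)`` times: commanded =
    R + (target_display_peak - adc_latency), display = R +
    target_display_peak.
    """
    cfg = cfg or SchedulerConfig()
    r = np.asarray(rpeaks.times, dtype=float)
    commanded = r + (cfg.target_display_peak - cfg.adc_latency)
    display = r + cfg.target_display_peak
    return commanded, display


def schedule_antiphase(inphase_peaks: np.ndarray, rpeaks: RPeakTrain) -> np.ndarray:
    """Anti-phase (diastole) pulse peaks.

    The pulse for beat i is delayed from the in-phase peak by half the
    preceding R-R interval, ``0.5 * (R_i - R_{i-1})``.  The first beat has
    no preceding interval and emits no anti-phase pulse.
    """
    r = np.asarray(rpeaks.times, dtype=float)
    peaks = np.asarray(inphase_peaks, dtype=float)
    if peaks.size != r.size:
        raise ValueError("need one in-phase peak per R-peak")
    if r.size < 2:
        return np.empty(0)
    return peaks[1:] + 0.5 * np.diff(r)


def render_pulse_trace(
    peaks: np.ndarray,
    cfg: SchedulerConfig | None = None,
    duration: float | None = None,
    command_times: np.ndarray | None = None,
):
    """Sample the Gaussian pulse train on the update and render grids.

    amplitude(t) = sum over peaks of exp(-(t - peak)^2 / (2 scale^2)).
    Overlapping pulses add.  If ``command_times`` is given, the trace is
    causal: a pulse contributes at grid time t only once commanded
    (command_times[j] <= t).  The rendered trace holds, at each render
    tick, the most recent update-grid value (sample-and-hold).

    Returns ``(update_times, amplitude, render_times, rendered)``.
    """
    cfg = cfg or SchedulerConfig()
    if duration is None or duration <= 0:
        raise ValueError("duration must be positive")
    peaks = np.asarray(peaks, dtype=float)
    ct = None
    if command_times is not None:
        ct = np.asarray(command_times, dtype=float)
        if ct.size != peaks.size:
            raise ValueError("need one command time per peak")
    t = np.arange(0.0, duration, 1.0 / cfg.update_rate)
    amp = np.zeros_like(t)
    halfw = 6.0 * cfg.pulse_scale  # Gaussian tail beyond 6 sigma is < 2e-8
    rate = cfg.update_rate
    for j, p in enumerate(peaks):
        lo_t = p - halfw if ct is None else max(p - halfw, ct[j])
        lo = max(0, int(np.ceil(lo_t * rate - 1e-9)))
        hi = min(t.size, int(np.floor((p + halfw) * rate)) + 1)
        if hi > lo:
            amp[lo:hi] += np.exp(-0.5 * ((t[lo:hi] - p) / cfg.pulse_scale) ** 2)
    tr = np.arange(0.0, duration, 1.0 / cfg.render_rate)
    # most recent update sample at or before each render tick
    idx = np.minimum((tr * cfg.update_rate + 1e-9).astype(int), t.size - 1)
    return t, amp, tr, amp[idx]


def replay_session(record: ECGRecord, cfg: SchedulerConfig | None = None) -> PulseSchedule:
    """Run the full causal chain on a recording.

    Streaming R-peak detection feeds in-phase scheduling, anti-phase
    scheduling, and trace rendering in a single pass; the result equals
    composing the batch operations on the streaming-detected peaks.
    """
    cfg = cfg or SchedulerConfig()
    # the batch path runs the identical causal (streaming-contract) chain
    # in vectorised form; see ecg.detect_rpeaks
    with np.errstate(all="ignore"):
        import warnings as _w

        with _w.catch_warnings():
            _w.simplefilter("ignore")
            rpeaks = detect_rpeaks(record, streaming=False)
    if len(rpeaks) == 0:
        empty = np.empty(0)
        return PulseSchedule(empty, empty, empty)
    commanded, display = schedule_inphase(rpeaks, cfg)
    anti = schedule_antiphase(display, rpeaks)
    duration = record.start_time + record.duration
    sched = PulseSchedule(display, anti, commanded)
    t, amp_in, tr, ren_in = render_pulse_trace(
        display, cfg, duration, command_times=rpeaks.times
    )
    if anti.size:
        # anti-phase pulse i is commanded once R_i is detected
        _, amp_anti, _, ren_anti = render_pulse_trace(
            anti, cfg, duration, command_times=rpeaks.times[1:]
        )
    else:
        amp_anti = np.zeros_like(t)
        ren_anti = np.zeros_like(ren_in)
    sched.update_times = t
    sched.amplitude_trace = {"inphase": amp_in, "antiphase": amp_anti}
    sched.render_times = tr
    sched.rendered_trace = {"inphase": ren_in, "antiphase": ren_anti}
    return sched
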