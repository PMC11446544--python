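"""ECG containers, filtering, streaming R-peak detection, and T-wave delineation.

The detection chain follows the classic Pan-Tompkins recipe: bandpass
(5-15 Hz), five-point differentiation, squaring, moving-window integration
(150 ms), then adaptive signal/noise thresholding with a 200 ms refractory
period and a search-back rule.  The chain is strictly causal, so the same
decision logic runs sample-by-sample (streaming) or over a full recording
(batch); the two modes produce identical peak trains by construction once
the 2 s threshold-learning period has elapsed.

T-wave offsets are delineated with a threshold-on-descending-limb rule on
the 0.5 Hz high-passed signal: within each beat the T extremum is located
in a physiological search window and the offset is the first sample after
the extremum at which the signal falls below 10% of the T amplitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps

__all__ = [
    "ECGRecord",
    "RPeakTrain",
    "CardiacEvents",
    "bandpass",
    "highpass_clean",
    "detect_rpeaks",
    "detect_t_offsets",
    "StreamingRPeakDetector",
]

#: Minimum physiological spacing between QRS complexes (s).
REFRACTORY_S = 0.2
#: Moving-window integration length (s).
INTEGRATION_WINDOW_S = 0.15
#: Threshold-learning period before peaks are emitted (s).
LEARNING_S = 2.0
#: Missed-beat search-back trigger, as a multiple of the running R-R mean.
SEARCHBACK_FACTOR = 1.66


@dataclass
class ECGRecord:
    """Single-channel ECG: ``samples`` at ``fs`` Hz starting at ``start_time`` s."""

    samples: np.ndarray
    fs: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("ECG samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("ECG samples must be finite")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclass
class RPeakTrain:
    """Ordered R-peak times (s) for one recording.

    Times are strictly increasing with successive differences of at least
    the QRS refractory period (200 ms).  ``fs`` records the sampling rate
    of the recording the peaks were detected on (provenance only).
    """

    times: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1:
            diffs = np.diff(self.times)
            if np.any(diffs < REFRACTORY_S - 1e-9):
                raise ValueError(
                    "R-peak train violates the 0.2 s refractory invariant"
                )

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def rr_intervals(self) -> np.ndarray:
        """Successive R-R intervals (s); length ``len(self) - 1``."""
        return np.diff(self.times)


@dataclass
class CardiacEvents:
    """Paired R-peak and T-wave-offset times delimiting systole/diastole.

    ``t_offsets[i]`` is the T-wave offset of beat ``i`` (NaN if the
    delineator found none, e.g. for the final beat); whenever defined it
    satisfies ``r_times[i] < t_offsets[i] < r_times[i + 1]``.
    """

    r_times: np.ndarray
    t_offsets: np.ndarray

    def __post_init__(self) -> None:
        self.r_times = np.asarray(self.r_times, dtype=float)
        self.t_offsets = np.asarray(self.t_offsets, dtype=float)
        if self.t_offsets.size != self.r_times.size:
            raise ValueError("need one t_offset slot per beat (NaN if missing)")
        ok = np.isfinite(self.t_offsets[:-1]) if self.r_times.size else np.array([])
        for i in np.flatnonzero(ok):
            if not (self.r_times[i] < self.t_offsets[i] < self.r_times[i + 1]):
                raise ValueError(
                    f"t_offset {self.t_offsets[i]:.3f} outside beat "
                    f"({self.r_times[i]:.3f}, {self.r_times[i + 1]:.3f})"
                )

    @property
    def n_missing(self) -> int:
        return int(np.sum(~np.isfinite(self.t_offsets)))


def _check_band(fs: float, *edges: float) -> None:
    nyq = fs / 2.0
    for e in edges:
        if not 0 < e < nyq:
            raise ValueError(f"filter edge {e} Hz outside (0, {nyq}) for fs={fs}")


def bandpass(
    record: ECGRecord, low: float = 5.0, high: float = 15.0, causal: bool = False
) -> ECGRecord:
    """QRS-enhancing bandpass (default 5-15 Hz).

    ``causal=False`` applies zero-phase forward-backward filtering (offline
    use); ``causal=True`` applies the one-pass filter used by the streaming
    detector.
    """
    _check_band(record.fs, low, high)
    if not low < high:
        raise ValueError("low cutoff must be below high cutoff")
    sos = sps.butter(2, [low, high], btype="bandpass", fs=record.fs, output="sos")
    if causal:
        out = sps.sosfilt(sos, record.samples)
    else:
        out = sps.sosfiltfilt(sos, record.samples)
    return ECGRecord(out, record.fs, record.start_time)


def highpass_clean(record: ECGRecord, cutoff: float = 0.5) -> ECGRecord:
    """Baseline-wander removal with a zero-phase high-pass (default 0.5 Hz)."""
    _check_band(record.fs, cutoff)
    sos = sps.butter(2, cutoff, btype="highpass", fs=record.fs, output="sos")
    return ECGRecord(sps.sosfiltfilt(sos, record.samples), record.fs, record.start_time)


def _pt_filters(fs: float):
    """Return (bandpass sos, derivative b, integration b) for the causal chain."""
    sos = sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos")
    # five-point derivative, Pan-Tompkins form (gain irrelevant to thresholds)
    deriv = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / 8.0
    n_int = max(1, int(round(INTEGRATION_WINDOW_S * fs)))
    integ = np.ones(n_int) / n_int
    return sos, deriv, integ


def _band_delay_samples(fs: float) -> int:
    """Group delay (samples) of the causal bandpass at its 10 Hz centre.

    The causal chain reports R times as the largest bandpassed deflection,
    which lags the true R-peak by the filter's group delay; detected times
    are shifted back by this known constant.
    """
    b, a = sps.sos2tf(sps.butter(2, [5.0, 15.0], btype="bandpass", fs=fs, output="sos"))
    _, gd = sps.group_delay((b, a), w=[10.0], fs=fs)
    return max(0, int(round(float(gd[0]))))


class _DecisionState:
    """Causal Pan-Tompkins thresholding over the integrated signal.

    Fed one sample at a time; shared verbatim between streaming and batch
    detection so the two agree exactly.  Peak times are refined to the
    largest-magnitude bandpassed sample in a short window ending at the
    integration peak.
    """

    def __init__(self, fs: float):
        self.fs = fs
        self.n_learn = int(round(LEARNING_S * fs))
        self.refractory = int(round(REFRACTORY_S * fs))
        # refinement window: integration window + 100 ms QRS allowance
        self.refine_win = int(round((INTEGRATION_WINDOW_S + 0.1) * fs))
        self.band_delay = _band_delay_samples(fs)
        self.spki = 0.0
        self.npki = 0.0
        self.initialized = False
        self.learn_buf: list[float] = []
        self.i = -1  # index of the most recent sample fed
        self.prev2 = 0.0
        self.prev1 = 0.0
        self.band_buf = np.zeros(self.refine_win + 2)
        self.last_qrs = -(10**9)
        self.rr_hist: list[float] = []
        self.noise_peaks: list[tuple[int, float]] = []
        self.peak_indices: list[int] = []

    @property
    def threshold(self) -> float:
        return self.npki + 0.25 * (self.spki - self.npki)

    def _refine(self, idx: int) -> int:
        """Locate the R sample as the max |bandpassed| ending at ``idx``."""
        lo = max(0, idx - self.refine_win)
        # band_buf is a rolling window whose last element is sample self.i
        offset = self.i - (self.band_buf.size - 1)
        a = max(lo - offset, 0)
        b = idx - offset + 1
        if b <= a:
            # peak predates the rolling buffer (search-back recovery):
            # fall back to the unrefined integration-peak index
            return idx
        seg = np.abs(self.band_buf[a:b])
        return offset + a + int(np.argmax(seg))

    def _accept(self, idx: int, val: float, searchback: bool) -> int | None:
        r = max(0, self._refine(idx) - self.band_delay)
        if self.peak_indices and (r - self.peak_indices[-1]) < self.refractory:
            return None
        if searchback:
            self.spki = 0.25 * val + 0.75 * self.spki
        else:
            self.spki = 0.125 * val + 0.875 * self.spki
        if self.peak_indices:
            self.rr_hist.append((r - self.peak_indices[-1]) / self.fs)
            self.rr_hist = self.rr_hist[-8:]
        self.peak_indices.append(r)
        self.last_qrs = idx
        self.noise_peaks = []
        return r

    def update(self, integ: float, band: float) -> list[int]:
        """Feed one sample; return indices of any newly confirmed R-peaks."""
        self.i += 1
        self.band_buf = np.roll(self.band_buf, -1)
        self.band_buf[-1] = band
        emitted: list[int] = []
        if not self.initialized:
            self.learn_buf.append(integ)
            if len(self.learn_buf) >= self.n_learn:
                arr = np.asarray(self.learn_buf)
                self.spki = float(arr.max())
                self.npki = 0.5 * float(arr.mean())
                self.initialized = True
                self.last_qrs = self.i
            self.prev2, self.prev1 = self.prev1, integ
            return emitted

        # local maximum of the integrated signal at the previous sample
        if self.prev1 > self.prev2 and self.prev1 >= integ:
            idx, val = self.i - 1, self.prev1
            if val > self.threshold:
                r = self._accept(idx, val, searchback=False)
                if r is not None:
                    emitted.append(r)
            else:
                self.npki = 0.125 * val + 0.875 * self.npki
                self.noise_peaks.append((idx, val))

        # search-back for a missed beat
        if self.rr_hist:
            rr_mean = float(np.mean(self.rr_hist))
            if (self.i - self.last_qrs) / self.fs > SEARCHBACK_FACTOR * rr_mean:
                cands = [
                    (idx, val)
                    for idx, val in self.noise_peaks
                    if val > 0.5 * self.threshold
                ]
                if cands:
                    idx, val = max(cands, key=lambda p: p[1])
                    r = self._accept(idx, val, searchback=True)
                    if r is not None:
                        emitted.append(r)
                else:
                    self.last_qrs = self.i  # re-arm rather than fire every sample

        self.prev2, self.prev1 = self.prev1, integ
        return emitted


class StreamingRPeakDetector:
    """Sample-by-sample R-peak detector (causal Pan-Tompkins).

    Each call to :meth:`process` consumes one ECG sample and returns the
    times (s) of any R-peaks confirmed by that sample.  Filter state is
    carried between calls, so feeding a recording sample-by-sample matches
    :func:`detect_rpeaks` in batch mode exactly.
    """

    def __init__(self, fs: float, start_time: float = 0.0):
        if fs < 50:
            raise ValueError("sampling rate below 50 Hz cannot resolve the QRS")
        self.fs = fs
        self.start_time = start_time
        sos, deriv, integ = _pt_filters(fs)
        self._sos = sos
        self._zi_sos = np.zeros((sos.shape[0], 2))
        self._b_deriv, self._zi_deriv = deriv, np.zeros(deriv.size - 1)
        self._b_int, self._zi_int = integ, np.zeros(integ.size - 1)
        self._state = _DecisionState(fs)

    def process(self, sample: float) -> list[float]:
        x = np.atleast_1d(float(sample))
        band, self._zi_sos = sps.sosfilt(self._sos, x, zi=self._zi_sos)
        d, self._zi_deriv = sps.lfilter(self._b_deriv, 1.0, band, zi=self._zi_deriv)
        sq = d * d
        integ, self._zi_int = sps.lfilter(self._b_int, 1.0, sq, zi=self._zi_int)
        new = self._state.update(float(integ[0]), float(band[0]))
        return [self.start_time + i / self.fs for i in new]

    def finalize(self) -> RPeakTrain:
        idx = np.sort(np.asarray(self._state.peak_indices, dtype=int))
        return RPeakTrain(self.start_time + idx / self.fs, self.fs)


def detect_rpeaks(record: ECGRecord, streaming: bool = False) -> RPeakTrain:
    """Detect R-peaks with the Pan-Tompkins chain.

    Parameters
    ----------
    record
        Single-channel ECG; at least 2 s long (the threshold-learning
        period).
    streaming
        If True, feed the recording through :class:`StreamingRPeakDetector`
        one sample at a time.  If False, run the identical causal chain
        vectorised over the whole recording.  The two modes agree exactly.
    """
    if record.duration < LEARNING_S:
        raise ValueError("recording must be at least 2 s for threshold learning")
    if record.fs < 50:
        raise ValueError("sampling rate below 50 Hz cannot resolve the QRS")

    if streaming:
        det = StreamingRPeakDetector(record.fs, record.start_time)
        for s in record.samples:
            det.process(s)
        train = det.finalize()
    else:
        sos, deriv, integ_b = _pt_filters(record.fs)
        band = sps.sosfilt(sos, record.samples)
        d = sps.lfilter(deriv, 1.0, band)
        integ = sps.lfilter(integ_b, 1.0, d * d)
        state = _DecisionState(record.fs)
        for i in range(record.samples.size):
            state.update(float(integ[i]), float(band[i]))
        idx = np.sort(np.asarray(state.peak_indices, dtype=int))
        train = RPeakTrain(record.start_time + idx / record.fs, record.fs)

    if len(train) == 0:
        warnings.warn("no R-peaks detected (flat or featureless signal)")
    return train


def detect_t_offsets(record: ECGRecord, rpeaks: RPeakTrain) -> CardiacEvents:
    """Delineate T-wave offsets between consecutive R-peaks.

    For each beat the T extremum is sought in the window
    (R + 150 ms, R + 60% of the R-R interval) of the 0.5 Hz high-passed
    signal; the offset is the first sample after the extremum at which the
    signal (with the T wave's polarity) drops below 10% of the T amplitude,
    measured above the post-T baseline (the minimum between the T peak and
    the next R-peak — high-pass filtering shifts the isoelectric line).
    Beats where the window is empty or no crossing occurs before the next
    R-peak get a NaN offset; the final beat has no following R-peak and is
    always NaN.
    """
    if len(rpeaks) < 2:
        raise ValueError("need at least 2 R-peaks to delineate T-waves")
    clean = highpass_clean(record).samples
    # the T-wave is a slow deflection; mild zero-phase Gaussian smoothing
    # (sigma 15 ms) keeps the threshold crossing off broadband noise
    clean = ndimage.gaussian_filter1d(clean, 0.015 * record.fs)
    t = record.times
    r = rpeaks.times
    offsets = np.full(r.size, np.nan)
    for i in range(r.size - 1):
        rr = r[i + 1] - r[i]
        lo_t, hi_t = r[i] + 0.15, r[i] + 0.6 * rr
        lo = int(np.searchsorted(t, lo_t, side="left"))
        hi = int(np.searchsorted(t, hi_t, side="right"))
        if hi - lo < 2:
            continue  # window too short (very fast rhythm)
        seg = clean[lo:hi]
        pk = int(np.argmax(np.abs(seg)))
        sign = 1.0 if seg[pk] >= 0 else -1.0
        # stop before the next QRS so it cannot pollute the baseline
        stop = int(np.searchsorted(t, r[i + 1] - 0.1, side="left"))
        tail = sign * clean[lo + pk : stop]
        if tail.size < 2:
            continue
        # amplitude measured from the post-T baseline (high-pass filtering
        # shifts the isoelectric line, so absolute zero is not a baseline);
        # a low percentile is robust to residual noise
        base = float(np.percentile(tail, 10))
        amp = float(tail[0]) - base
        if amp <= 0:
            continue
        below = np.flatnonzero(tail < base + 0.1 * amp)
        if below.size == 0:
            continue
        off = t[lo + pk + below[0]]
        if r[i] < off < r[i + 1]:
            offsets[i] = off
    return CardiacEvents(r[:], offsets)
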