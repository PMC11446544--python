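"""Filtering, Pan-Tompkins detection, and T-wave delineation contracts."""

import warnings

import numpy as np
import pytest
from scipy import signal as sps

import cardiorivalry as cr
from cardiorivalry.ecg import ECGRecord, StreamingRPeakDetector


def _sine(freq, fs=100.0, duration=20.0):
    t = np.arange(0.0, duration, 1.0 / fs)
    return t, np.sin(2 * np.pi * freq * t)


def _gain(record_out, x_in):
    # steady-state RMS amplitude ratio, transient discarded
    n = x_in.size // 4
    out, ref = record_out.samples[n:-n], x_in[n:-n]
    return np.sqrt(np.mean(out**2) / np.mean(ref**2))


class TestBandpass:
    def test_dc_rejection(self):
        rec = ECGRecord(np.ones(2000), 100)
        out = cr.bandpass(rec, causal=True)
        assert np.abs(out.samples[-100:]).max() < 1e-3

    @pytest.mark.parametrize(
        "freq,lo,hi", [(10.0, 0.7, 1.1), (1.0, 0.0, 0.3)]
    )
    def test_frequency_response(self, freq, lo, hi):
        t, x = _sine(freq)
        out = cr.bandpass(ECGRecord(x, 100))
        # oracle: evaluate the designed filter's transfer function
        sos = sps.butter(2, [5, 15], btype="bandpass", fs=100, output="sos")
        w, h = sps.sosfreqz(sos, worN=[freq], fs=100)
        expected = np.abs(h[0]) ** 2  # zero-phase = squared magnitude
        g = _gain(out, x)
        assert lo <= g <= hi
        assert g == pytest.approx(expected, abs=0.05)

    def test_double_filtering_squares_response(self):
        t, x = _sine(10.0)
        rec = ECGRecord(x, 100)
        once = cr.bandpass(rec, causal=True)
        twice = cr.bandpass(once, causal=True)
        g1, g2 = _gain(once, x), _gain(twice, x)
        assert g2 == pytest.approx(g1**2, rel=0.05)

    def test_band_outside_nyquist_rejected(self):
        rec = ECGRecord(np.zeros(100), 100)
        with pytest.raises(ValueError):
            cr.bandpass(rec, low=5, high=60)


class TestHighpass:
    def test_linear_drift_removed(self):
        drift = np.linspace(0.0, 10.0, 6000)
        out = cr.highpass_clean(ECGRecord(drift, 100))
        n = drift.size // 4
        assert np.abs(out.samples[n:-n]).max() < 0.05 * 10.0

    def test_zero_in_zero_out(self):
        out = cr.highpass_clean(ECGRecord(np.zeros(1000), 100))
        np.testing.assert_allclose(out.samples, 0.0)

    def test_passband_gain(self):
        t, x = _sine(10.0)
        out = cr.highpass_clean(ECGRecord(x, 100))
        assert _gain(out, x) >= 0.95


class TestRPeakDetection:
    def _match_stats(self, detected, truth, tol=0.05, skip_until=2.0):
        truth = truth[truth > skip_until]
        d = np.abs(detected[:, None] - truth[None, :])
        hit = d.min(axis=0) < tol
        extra = (np.abs(detected[:, None] - truth[None, :]).min(axis=1) > tol).sum()
        return hit.mean(), int(extra)

    def test_closed_loop_recovery(self):
        train = cr.simulate_rr_series(0.8, 0.05, 600, seed=31)
        record, _ = cr.simulate_ecg(train, fs=100, noise_sd=0.05, seed=32)
        det = cr.detect_rpeaks(record)
        frac, extra = self._match_stats(det.times, train.times)
        assert frac >= 0.99
        # no spurious detections once thresholds have adapted
        assert extra <= np.sum(train.times <= 2.0)

    def test_refractory_suppresses_close_beats(self):
        # two QRS complexes 0.15 s apart: the second is inside the
        # refractory period and must be suppressed
        fs = 100.0
        t = np.arange(0, 20, 1 / fs)
        x = np.zeros_like(t)
        for rt in np.arange(1.0, 19.0, 1.0):
            x += np.exp(-0.5 * ((t - rt) / 0.015) ** 2)
            x += np.exp(-0.5 * ((t - rt - 0.15) / 0.015) ** 2)
        det = cr.detect_rpeaks(ECGRecord(x, fs))
        assert np.all(np.diff(det.times) >= 0.2 - 1e-9)
        # at most one detection per doublet
        assert len(det) <= 18

    def test_amplitude_scale_invariance(self, noisy_ecg):
        record, _ = noisy_ecg
        det1 = cr.detect_rpeaks(record)
        det10 = cr.detect_rpeaks(
            ECGRecord(10.0 * record.samples, record.fs, record.start_time)
        )
        np.testing.assert_array_equal(det1.times, det10.times)

    def test_streaming_equals_batch(self, noisy_ecg):
        record, _ = noisy_ecg
        batch = cr.detect_rpeaks(record, streaming=False)
        stream = cr.detect_rpeaks(record, streaming=True)
        np.testing.assert_array_equal(batch.times, stream.times)

    def test_streaming_emission_is_causal(self, clean_ecg):
        record, _ = clean_ecg
        det = StreamingRPeakDetector(record.fs, record.start_time)
        emitted = []
        for i, s in enumerate(record.samples):
            now = record.start_time + i / record.fs
            for pt in det.process(s):
                assert pt <= now + 1e-9  # peaks refer to past samples only
                emitted.append(pt)
        assert len(emitted) > 100

    def test_flat_signal_warns_empty(self):
        with pytest.warns(UserWarning):
            det = cr.detect_rpeaks(ECGRecord(np.zeros(1000), 100))
        assert len(det) == 0

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            cr.detect_rpeaks(ECGRecord(np.zeros(100), 100))


class TestTOffsets:
    def test_accuracy_against_ground_truth(self):
        train = cr.simulate_rr_series(0.8, 0.05, 300, seed=41)
        for noise in (0.0, 0.02):
            record, truth = cr.simulate_ecg(train, noise_sd=noise, seed=42)
            det = cr.detect_rpeaks(record)
            ev = cr.detect_t_offsets(record, det)
            est = ev.t_offsets[np.isfinite(ev.t_offsets)]
            ref = truth.t_offsets[np.isfinite(truth.t_offsets)]
            err = np.abs(est[:, None] - ref[None, :]).min(axis=1)
            assert err.mean() <= 0.030

    def test_last_beat_missing(self, clean_ecg):
        record, _ = clean_ecg
        det = cr.detect_rpeaks(record)
        ev = cr.detect_t_offsets(record, det)
        assert not np.isfinite(ev.t_offsets[-1])

    def test_offsets_strictly_inside_beats(self, noisy_ecg):
        record, _ = noisy_ecg
        det = cr.detect_rpeaks(record)
        ev = cr.detect_t_offsets(record, det)
        ok = np.isfinite(ev.t_offsets[:-1])
        assert ok.sum() > 0
        assert np.all(ev.t_offsets[:-1][ok] > ev.r_times[:-1][ok])
        assert np.all(ev.t_offsets[:-1][ok] < ev.r_times[1:][ok])

    def test_too_few_peaks_rejected(self, clean_ecg):
        record, _ = clean_ecg
        with pytest.raises(ValueError):
            cr.detect_t_offsets(record, cr.RPeakTrain(np.array([1.0]), 100))
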