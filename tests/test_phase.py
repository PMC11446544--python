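"""Cardiac-angle mapping and circular bootstrap summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cardiorivalry as cr
from cardiorivalry.ecg import CardiacEvents
from cardiorivalry.phase import _wrap


@pytest.fixture
def events():
    return CardiacEvents(
        np.array([0.0, 0.8, 1.6, 2.4]),
        np.array([0.3, np.nan, 1.9, np.nan]),
    )


class TestCardiacAngle:
    def test_t_offset_maps_to_zero(self, events):
        a, _ = cr.cardiac_angle([0.3], events)
        assert a[0] == pytest.approx(0.0, abs=1e-12)

    def test_midpoints_map_to_quarter_turns(self, events):
        a, _ = cr.cardiac_angle([0.15, 0.55], events)
        np.testing.assert_allclose(a, [-np.pi / 2, np.pi / 2], atol=1e-12)

    def test_r_peak_maps_to_minus_pi(self, events):
        a, _ = cr.cardiac_angle([0.0], events)
        assert a[0] == pytest.approx(-np.pi)

    def test_missing_t_offset_drops_event(self, events):
        a, dropped = cr.cardiac_angle([1.0], events)  # beat 1 has no T-offset
        assert a.size == 0
        assert dropped == 1

    def test_event_outside_span_dropped_with_warning(self, events):
        with pytest.warns(UserWarning):
            a, dropped = cr.cardiac_angle([5.0, 0.3], events)
        assert a.size == 1
        assert dropped == 1

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        times=st.lists(
            st.floats(0.0, 0.799), min_size=2, max_size=12, unique=True
        )
    )
    def test_monotone_within_beat(self, times):
        ev = CardiacEvents(
            np.array([0.0, 0.8, 1.6]), np.array([0.3, 1.1, np.nan])
        )
        t = np.sort(np.asarray(times))
        a, _ = cr.cardiac_angle(t, ev)
        assert np.all(np.diff(a) >= 0)


class TestCircularMean:
    def test_symmetric_pair_cancels(self):
        assert cr.circular_mean([np.pi / 4, -np.pi / 4]) == pytest.approx(0.0)

    def test_identical_angles_identity(self):
        assert cr.circular_mean([1.2, 1.2, 1.2]) == pytest.approx(1.2)

    def test_resultant_vector_fixture(self):
        # sin sum = 1, cos sum = 0 -> mean at pi/2
        assert cr.circular_mean([0.0, np.pi / 2, np.pi]) == pytest.approx(
            np.pi / 2
        )

    def test_zero_resultant_raises(self):
        with pytest.raises(ValueError):
            cr.circular_mean([0.0, np.pi])

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        shift=st.floats(-np.pi, np.pi),
        angles=st.lists(st.floats(-1.0, 1.0), min_size=2, max_size=10),
    )
    def test_rotation_equivariance(self, shift, angles):
        a = np.asarray(angles)
        m0 = cr.circular_mean(a)
        m1 = cr.circular_mean(a + shift)
        assert _wrap(m1 - m0 - shift) == pytest.approx(0.0, abs=1e-9)


class TestSubjectBootstrap:
    def test_zero_spread_zero_width(self):
        s = cr.subject_bootstrap(np.full(20, 0.7), n_boot=200, seed=0)
        assert s.ci_high - s.ci_low == pytest.approx(0.0, abs=1e-12)
        assert s.mean_angle == pytest.approx(0.7)

    def test_ci_contains_point_estimate(self):
        rng = np.random.default_rng(0)
        a = rng.vonmises(1.0, 4.0, 100)
        s = cr.subject_bootstrap(a, n_boot=1000, seed=1)
        assert s.ci_low <= s.mean_angle <= s.ci_high

    def test_coverage_calibration(self):
        # ~95% of bootstrap CIs should cover the true von Mises mean
        rng = np.random.default_rng(7)
        mu, n_sim = 1.0, 500
        hits = 0
        for i in range(n_sim):
            a = rng.vonmises(mu, 4.0, 200)
            s = cr.subject_bootstrap(a, n_boot=500, seed=i)
            hits += s.ci_low <= mu <= s.ci_high
        assert 0.92 <= hits / n_sim <= 0.98


class TestGroupBootstrap:
    def test_degenerate_subjects_zero_width(self):
        sets = [np.full(2, 0.4) for _ in range(5)]
        s = cr.group_bootstrap(sets, n_boot=200, seed=0)
        assert s.mean_angle == pytest.approx(0.4)
        assert s.ci_high - s.ci_low == pytest.approx(0.0, abs=1e-12)

    def test_hierarchical_ci_wider_than_pooled(self):
        rng = np.random.default_rng(3)
        wider = 0
        n_sim = 40
        for i in range(n_sim):
            mus = rng.normal(1.0, 0.5, 5)
            sets = [rng.vonmises(m, 8.0, 60) for m in mus]
            g = cr.group_bootstrap(sets, n_boot=800, seed=i)
            pooled = cr.subject_bootstrap(
                np.concatenate(sets), n_boot=800, seed=i
            )
            wider += (g.ci_high - g.ci_low) >= (pooled.ci_high - pooled.ci_low)
        assert wider / n_sim >= 0.95

    def test_invariant_to_subject_ordering(self):
        rng = np.random.default_rng(5)
        sets = [rng.vonmises(0.5, 4.0, 30) for _ in range(6)]
        s1 = cr.group_bootstrap(sets, n_boot=500, seed=9)
        s2 = cr.group_bootstrap(sets[::-1], n_boot=500, seed=9)
        assert s1.mean_angle == s2.mean_angle
        assert (s1.ci_low, s1.ci_high) == (s2.ci_low, s2.ci_high)


class TestManipulationCheck:
    def test_negative_control_fails(self):
        rng = np.random.default_rng(1)
        ds = {
            0: {
                "inphase": rng.vonmises(-1.2, 6.0, 100),
                "antiphase": rng.vonmises(-1.0, 6.0, 100),  # forced into systole
            }
        }
        table, ok = cr.manipulation_check(ds, n_boot=200, seed=0)
        assert not ok
        assert not table.loc[0, "ok"]

    def test_missing_stream_flagged_incomplete(self):
        ds = {0: {"inphase": np.array([-1.0, -1.1])}}
        table, ok = cr.manipulation_check(ds, n_boot=100, seed=0)
        assert not ok
        assert not table.loc[0, "complete"]

    def test_well_separated_streams_pass(self):
        rng = np.random.default_rng(2)
        ds = {
            s: {
                "inphase": rng.vonmises(-1.3, 6.0, 150),
                "antiphase": rng.vonmises(1.8, 6.0, 150),
            }
            for s in range(4)
        }
        table, ok = cr.manipulation_check(ds, n_boot=300, seed=0)
        assert ok
        assert table["ok"].all()
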