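"""Fixation detection, AOI dwell and event time-courses."""

import numpy as np
import pytest

import cbdrive as cb
from cbdrive.gaze import DEFAULT_MAX_DUR_S, DEFAULT_MIN_DUR_S

from idt_oracle import oracle_idt
from conftest import make_gaze, random_trace


class TestAngularSeparation:
    def test_identical_and_orthogonal(self):
        assert cb.angular_separation([1, 0, 0], [1, 0, 0]) == 0.0
        assert cb.angular_separation([1, 0, 0], [0, 1, 0]) == pytest.approx(90.0)

    def test_one_degree_closed_form(self):
        a = np.array([1.0, 0.0, 0.0])
        b = np.array([np.cos(np.radians(1.0)), np.sin(np.radians(1.0)), 0.0])
        assert cb.angular_separation(a, b) == pytest.approx(1.0, abs=1e-9)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cb.angular_separation([0, 0, 0], [1, 0, 0])


class TestDetectFixations:
    def test_constant_direction_single_fixation(self):
        t = np.arange(0, 0.3, 1 / 120)
        g = make_gaze(t, np.zeros(t.size))
        fx = cb.detect_fixations(g)
        assert len(fx) == 1
        assert fx[0].duration_s == pytest.approx(t[-1] - t[0])
        assert fx[0].dispersion_deg == pytest.approx(0.0, abs=1e-9)

    def test_alternating_large_steps_no_fixations(self):
        t = np.arange(0, 1.0, 1 / 120)
        az = np.where(np.arange(t.size) % 2 == 0, 5.0, -5.0)
        assert cb.detect_fixations(make_gaze(t, az)) == []

    def test_two_plateaus_with_transit_match_oracle(self):
        # two 250 ms plateaus 3 degrees apart joined by one transit sample
        t = np.arange(0, 0.5 + 1.5 / 120, 1 / 120)
        az = np.zeros(t.size)
        half = t.size // 2
        az[half] = 1.5  # transit sample between the plateaus
        az[half + 1 :] = 3.0
        g = make_gaze(t, az)
        fx = cb.detect_fixations(g, dispersion_deg=1.0)
        ref = oracle_idt(g.t, g.gaze_dir, g.valid, 1.0)
        assert len(fx) == len(ref) == 2
        for f, (i, j) in zip(fx, ref):
            assert f.start_t == pytest.approx(g.t[i])
            assert f.end_t == pytest.approx(g.t[j])

    def test_fewer_than_two_samples_empty(self):
        g = make_gaze([0.0], [0.0])
        assert cb.detect_fixations(g) == []

    def test_non_monotone_time_rejected(self):
        g = make_gaze([0.0, 0.2, 0.1], [0, 0, 0])
        with pytest.raises(cb.ValidationError):
            cb.detect_fixations(g)

    def test_long_window_split_within_duration_band(self):
        t = np.arange(0, 1.7, 1 / 120)
        fx = cb.detect_fixations(make_gaze(t, np.zeros(t.size)))
        assert len(fx) >= 3
        for f in fx:
            assert DEFAULT_MIN_DUR_S <= f.duration_s <= DEFAULT_MAX_DUR_S + 1e-9
        # splitting preserves the whole stretch: contiguous coverage
        assert fx[0].start_t == pytest.approx(t[0])
        assert fx[-1].end_t == pytest.approx(t[-1])

    def test_invalid_samples_break_window(self):
        t = np.arange(0, 0.4, 1 / 120)
        valid = np.ones(t.size, bool)
        valid[t.size // 2] = False
        fx = cb.detect_fixations(make_gaze(t, np.zeros(t.size), valid=valid))
        assert len(fx) == 2

    @pytest.mark.parametrize("seed", range(200))
    def test_oracle_equivalence_random_traces(self, seed):
        """I-DT must equal the exhaustive maximal-window oracle."""
        rng = np.random.default_rng(seed)
        g = random_trace(rng, irregular=True, invalid_p=0.03)
        thr = float(rng.uniform(0.7, 1.3))
        fx = cb.detect_fixations(g, dispersion_deg=thr)
        ref = oracle_idt(g.t, g.gaze_dir, g.valid, thr)
        got = [(f.start_t, f.end_t) for f in fx]
        want = [(g.t[i], g.t[j]) for i, j in ref]
        assert got == pytest.approx(want)

    def test_dispersion_monotonicity(self):
        """A larger threshold never decreases total fixation time."""
        rng = np.random.default_rng(7)
        g = random_trace(rng, n=1500)
        totals = []
        for thr in (0.7, 1.0, 1.3, 2.0):
            fx = cb.detect_fixations(g, dispersion_deg=thr, split_long=False)
            totals.append(sum(f.duration_s for f in fx))
        assert all(b >= a - 1e-12 for a, b in zip(totals, totals[1:]))


def _aoi_at(az_deg, dist=10.0, radius=0.5, t0=-10.0, t1=10.0):
    az = np.radians(az_deg)
    c = dist * np.array([np.sin(az), 0.0, np.cos(az)])
    return cb.AOI(
        aoi_id="a",
        kind="object",
        track_t=np.array([t0, t1]),
        track_center=np.stack([c, c]),
        radius=radius,
    )


class TestAoiDwell:
    def test_fixation_on_center_fully_returned(self):
        t = np.arange(0, 0.3, 1 / 120)
        g = make_gaze(t, np.zeros(t.size))
        fx = cb.detect_fixations(g)
        hits = cb.aoi_dwell(fx, g, _aoi_at(0.0), (0.0, 0.3))
        assert len(hits) == 1
        assert hits[0] == pytest.approx((fx[0].start_t, fx[0].end_t))

    def test_offset_twice_angular_radius_misses(self):
        t = np.arange(0, 0.3, 1 / 120)
        g = make_gaze(t, np.zeros(t.size))
        fx = cb.detect_fixations(g)
        ang_radius = np.degrees(np.arctan(0.5 / 10.0))
        assert cb.aoi_dwell(fx, g, _aoi_at(2 * ang_radius), (0.0, 0.3)) == []

    def test_window_outside_track_raises(self):
        t = np.arange(0, 0.3, 1 / 120)
        g = make_gaze(t, np.zeros(t.size))
        with pytest.raises(cb.CoverageError):
            cb.aoi_dwell([], g, _aoi_at(0.0, t0=0.0, t1=0.1), (0.0, 0.3))

    def test_simulated_pre_gaze_contract(self, default_schedule):
        """p_gaze_pre = 1 implies >= 100 ms pre-window dwell on every
        behaviour change's AOI."""
        import dataclasses

        _, events, bounds = default_schedule
        params = dataclasses.replace(
            cb.default_params(),
            p_gaze_pre={k: 1.0 for k in cb.CHANGE_TYPES},
            p_gaze_post={k: 1.0 for k in cb.CHANGE_TYPES},
        )
        s = cb.simulate_session(params, events, bounds, seed=5, group="C")
        fx = cb.detect_fixations(s.gaze)
        for e in s.events:
            if not e.is_behaviour:
                continue
            tc = cb.event_timecourse(fx, s.gaze, e, s.aois[e.aoi_id])
            assert tc.dwell_pre_ms >= 100.0
            assert tc.dwell_post_ms >= 100.0


class TestEventTimecourse:
    def _event(self, t0):
        return cb.ChangeEvent(
            change_id="c", pair_id="p", change_type="property", complexity="low",
            trigger_t=t0, aoi_id="a", gap_s=0.0, encounter_index=0,
        )

    def test_full_on_aoi_all_bins_full(self):
        t = np.arange(0, 16.0, 1 / 120)
        g = make_gaze(t, np.zeros(t.size))
        fx = [cb.Fixation(0.0, 16.0, np.array([0.0, 0.0, 1.0]), 0.0)]
        tc = cb.event_timecourse(fx, g, self._event(8.0), _aoi_at(0.0, t0=0, t1=16))
        assert tc.bins_ms == pytest.approx(np.full(8, 1000.0))
        assert tc.dwell_pre_ms == pytest.approx(4000.0)
        assert tc.dwell_post_ms == pytest.approx(4000.0)

    def test_no_dwell_all_zero(self):
        t = np.arange(0, 16.0, 1 / 120)
        g = make_gaze(t, np.zeros(t.size))
        tc = cb.event_timecourse([], g, self._event(8.0), _aoi_at(0.0, t0=0, t1=16))
        assert tc.bins_ms == pytest.approx(np.zeros(8))

    def test_boundary_straddling_fixation_split_between_bins(self):
        t = np.arange(0, 16.0, 1 / 120)
        g = make_gaze(t, np.zeros(t.size))
        fx = [cb.Fixation(7.5, 8.5, np.array([0.0, 0.0, 1.0]), 0.0)]
        tc = cb.event_timecourse(fx, g, self._event(8.0), _aoi_at(0.0, t0=0, t1=16))
        assert tc.bins_ms[3] == pytest.approx(500.0)
        assert tc.bins_ms[4] == pytest.approx(500.0)
        assert tc.bins_ms[[0, 1, 2, 5, 6, 7]] == pytest.approx(np.zeros(6))

    def test_dwell_conservation(self, small_session, small_fixations):
        """Bin sums equal total clipped dwell exactly, for every change."""
        s = small_session
        for e in s.events:
            aoi = s.aois[e.aoi_id]
            tc = cb.event_timecourse(small_fixations, s.gaze, e, aoi)
            ivs = cb.aoi_dwell(
                small_fixations, s.gaze, aoi, (e.trigger_t - 4.0, e.trigger_t + 4.0)
            )
            total = 1000.0 * sum(hi - lo for lo, hi in ivs)
            assert tc.bins_ms.sum() == pytest.approx(total, abs=1e-9)
            assert tc.dwell_pre_ms + tc.dwell_post_ms == pytest.approx(total, abs=1e-9)
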