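"""Gaze categories, LBFTS, slopes, driving metrics and derived tables."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import cbdrive as cb
from cbdrive.coding import TrialOutcome
from conftest import recovery_params


class TestGazeCategory:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [
            (150, 150, "both"),
            (150, 50, "before_only"),
            (50, 150, "after_only"),
            (0, 0, "none"),
            (100, 99.9, "before_only"),  # threshold is >= 100 ms
        ],
    )
    def test_classification(self, pre, post, expected):
        assert cb.gaze_category(pre, post) == expected

    def test_negative_dwell_rejected(self):
        with pytest.raises(ValueError):
            cb.gaze_category(-1, 50)


def _outcome(detected, pre, post):
    return TrialOutcome(
        change_id="c",
        change_type="property",
        complexity="low",
        gap_s=0.0,
        encounter_index=0,
        pair_id="p",
        detected=detected,
        dwell_pre_ms=pre,
        dwell_post_ms=post,
    )


class TestLbfts:
    def test_miss_with_both_windows_is_lbfts(self):
        assert cb.classify_lbfts(_outcome(False, 150, 150)) is True

    def test_detection_never_lbfts(self):
        assert cb.classify_lbfts(_outcome(True, 150, 150)) is False

    def test_post_only_gaze_not_lbfts(self):
        assert cb.classify_lbfts(_outcome(False, 0, 150)) is False

    def test_shorter_pre_window_never_gains_gazers(self, small_session, small_fixations):
        """Narrowing the pre window 4 s -> 2 s cannot add both-window gazers."""
        s = small_session
        wide = cb.LbftsConfig(pre_window_s=4.0)
        narrow = cb.LbftsConfig(pre_window_s=2.0)
        n_wide = n_narrow = 0
        for e in s.events:
            tc = cb.event_timecourse(small_fixations, s.gaze, e, s.aois[e.aoi_id])
            for cfg, bump in ((wide, "w"), (narrow, "n")):
                pre, post = tc.dwell_window_ms(cfg.pre_window_s, cfg.post_window_s)
                if cb.gaze_category(pre, post, cfg.min_dwell_ms) == "both":
                    if bump == "w":
                        n_wide += 1
                    else:
                        n_narrow += 1
        assert n_narrow <= n_wide

    def test_forced_limits_in_cohort(self):
        params = dataclasses.replace(
            recovery_params(0.0),
            p_gaze_pre={k: 1.0 for k in cb.CHANGE_TYPES},
            p_gaze_post={k: 1.0 for k in cb.CHANGE_TYPES},
        )
        sessions = cb.simulate_cohort(2, params, seed=6)
        res = cb.process_sessions(sessions, cb.PipelineConfig(cutoff_mode="paper_default"))
        tab = cb.lbfts_table(res.outcomes, "both_gazers")
        assert (tab["rate_pct"] == 100.0).all()
        # with guaranteed detection instead, LBFTS vanishes
        params1 = dataclasses.replace(params, p_detect={k: 1.0 for k in params.p_detect})
        sessions1 = cb.simulate_cohort(2, params1, seed=6)
        res1 = cb.process_sessions(
            sessions1, cb.PipelineConfig(cutoff_mode="fixed", fixed_cutoff_s=10.0)
        )
        tab1 = cb.lbfts_table(res1.outcomes, "both_gazers")
        assert (tab1["rate_pct"] == 0.0).all()

    def test_category_partition_and_lbfts_subset(self, small_session, small_fixations):
        res = cb.process_sessions([small_session], cb.PipelineConfig())
        df = res.outcomes
        counts = df["gaze_category"].value_counts()
        assert counts.sum() == 72
        lb = df[df["lbfts"].astype(bool)]
        assert (~lb["detected"]).all()
        assert (lb["gaze_category"] == "both").all()


class TestRocSlopes:
    def test_flat_rates_zero_slopes(self):
        assert cb.roc_slopes([60.0, 60.0, 60.0]) == {
            "low_to_medium": 0.0,
            "medium_to_high": 0.0,
            "mean": 0.0,
        }

    def test_percentage_point_differences(self):
        sl = cb.roc_slopes([60.0, 56.1, 47.08])
        assert sl["low_to_medium"] == pytest.approx(-3.9)
        assert sl["medium_to_high"] == pytest.approx(-9.02)
        assert sl["mean"] == pytest.approx(-6.46)

    def test_additivity(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            r = rng.uniform(10, 90, size=3)
            sl = cb.roc_slopes(list(r))
            assert sl["low_to_medium"] + sl["medium_to_high"] == pytest.approx(r[2] - r[0])

    def test_missing_level_rejected(self):
        with pytest.raises(ValueError):
            cb.roc_slopes({"low": 60.0, "medium": 55.0})


class TestDrivingMetrics:
    def test_rising_edges(self):
        d = cb.DrivingStream(
            t=np.arange(7.0),
            speed_kmh=np.full(7, 20.0),
            brake=np.array([0, 0, 1, 1, 0, 0, 1], dtype=bool),
        )
        m = cb.driving_metrics(d, {"low": (0.0, 7.0)})
        assert m["low"].brake_hits == 2

    def test_constant_speed_average(self):
        d = cb.DrivingStream(
            t=np.arange(0, 60.0, 0.5),
            speed_kmh=np.full(120, 26.0),
            brake=np.zeros(120, bool),
        )
        m = cb.driving_metrics(d, {"low": (0.0, 60.0)})
        assert m["low"].avg_speed_kmh == pytest.approx(26.0)
        assert m["low"].completion_min == pytest.approx(1.0)

    def test_empty_segment_absent(self):
        d = cb.DrivingStream(t=np.arange(5.0), speed_kmh=np.full(5, 10.0), brake=np.zeros(5, bool))
        m = cb.driving_metrics(d, {"low": (0.0, 5.0), "high": (100.0, 200.0)})
        assert "high" not in m

    def test_poisson_brake_rate_recovered(self):
        """5 brake presses/min over a 6 min segment: hits near Poisson(30)."""
        params = dataclasses.replace(
            cb.default_params(),
            brake_rate_per_min={"low": 5.0, "medium": 5.0, "high": 5.0},
        )
        bounds = {"low": (0.0, 360.0), "medium": (360.0, 720.0), "high": (720.0, 1080.0)}
        hits = []
        for seed in range(30):
            rng_stream = cb.simulate_session(
                params,
                [],
                bounds,
                seed=seed,
                group="C",
                include_gaze=False,
            ).driving
            m = cb.driving_metrics(rng_stream, bounds)
            hits.append(m["low"].brake_hits)
        lo, hi = sps.poisson.ppf([0.025, 0.975], 30.0)
        assert lo <= np.mean(hits) <= hi


class TestTemporalProximity:
    def test_always_six_rows(self):
        sessions = cb.simulate_cohort(2, recovery_params(0.5), seed=3, include_gaze=False)
        res = cb.process_sessions(sessions, cb.PipelineConfig(cutoff_mode="paper_default"))
        tab = cb.temporal_proximity_table(res.outcomes)
        assert list(tab["gap_s"]) == [0.0, 1.0, 2.0, 4.0, 6.0, 8.0]

    def test_all_detected_rows_100(self):
        sessions = cb.simulate_cohort(2, recovery_params(1.0), seed=3, include_gaze=False)
        res = cb.process_sessions(
            sessions, cb.PipelineConfig(cutoff_mode="fixed", fixed_cutoff_s=10.0)
        )
        tab = cb.temporal_proximity_table(res.outcomes)
        assert tab["rate_pct"].to_numpy() == pytest.approx(np.full(6, 100.0))

    def test_gap0_penalty_detected(self):
        """A generator with a low 0 s-gap detection probability yields the
        lowest estimated rate at gap 0."""
        params = dataclasses.replace(
            recovery_params(0.4),
            p_detect_property_gap_mult={0.0: 0.25 / 0.4, 1.0: 1, 2.0: 1, 4.0: 1, 6.0: 1, 8.0: 1},
        )
        sessions = cb.simulate_cohort(30, params, seed=11, include_gaze=False)
        res = cb.process_sessions(
            sessions, cb.PipelineConfig(cutoff_mode="fixed", fixed_cutoff_s=10.0)
        )
        tab = cb.temporal_proximity_table(res.outcomes)
        rates = dict(zip(tab["gap_s"], tab["rate_pct"]))
        assert rates[0.0] == min(rates.values())

    def test_unknown_gap_rejected(self):
        df = pd.DataFrame(
            {
                "change_type": ["property"],
                "gap_s": [3.0],
                "detected": [True],
                "participant_id": ["p0"],
            }
        )
        with pytest.raises(cb.ValidationError):
            cb.temporal_proximity_table(df)


class TestLearningEffect:
    def test_deterministic_detection_identical_rates(self):
        sessions = cb.simulate_cohort(3, recovery_params(1.0), seed=9, include_gaze=False)
        res = cb.process_sessions(
            sessions, cb.PipelineConfig(cutoff_mode="fixed", fixed_cutoff_s=10.0)
        )
        tab = cb.learning_effect(res.outcomes)
        assert tab["first_rate_pct"].to_numpy() == pytest.approx(tab["last_rate_pct"].to_numpy())

    def test_missing_block_rejected(self):
        df = pd.DataFrame(
            {
                "change_type": ["property"] * 4,
                "segment_order": [0, 0, 1, 1],
                "participant_id": ["p0"] * 4,
                "detected": [True, False, True, False],
                "dwell_pre_ms": [0.0] * 4,
                "dwell_post_ms": [0.0] * 4,
            }
        )
        with pytest.raises(cb.ValidationError):
            cb.learning_effect(df)
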