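import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ewsmon import (
    EWSDetector,
    EWSProfile,
    compute_baseline,
    compute_weights,
    detect_alerts,
    score_stream,
)
from ewsmon.engine import (
    InsufficientBaselineError,
    NoMonitorableItemsError,
    ScorePoint,
    ScoringError,
)

from .conftest import STUDY_START, UTC


def t(day: float) -> dt.datetime:
    return dt.datetime.combine(STUDY_START, dt.time.min, tzinfo=UTC) + dt.timedelta(days=day)


def points(*day_score_pairs):
    return [ScorePoint(t(d), s) for d, s in day_score_pairs]


class TestComputeWeights:
    def test_tier_shares_are_20_30_50(self):
        assert compute_weights({"A": 3, "B": 2, "C": 1, "D": 0}) == {
            "A": 0.50,
            "B": 0.30,
            "C": 0.20,
            "D": 0.0,
        }

    def test_equal_split_within_a_tier(self):
        w = compute_weights({"A": 3, "B": 3, "C": 2, "D": 1})
        assert w == {"A": 0.25, "B": 0.25, "C": 0.30, "D": 0.20}

    def test_empty_tier_share_renormalized_proportionally(self):
        w = compute_weights({"A": 3, "B": 2})
        assert w["A"] == pytest.approx(0.5 / 0.8)
        assert w["B"] == pytest.approx(0.3 / 0.8)

    def test_all_zero_relevance_is_an_error(self):
        with pytest.raises(NoMonitorableItemsError):
            compute_weights({"A": 0, "B": 0})

    def test_out_of_range_relevance_rejected(self):
        with pytest.raises(ValueError, match="relevance"):
            compute_weights({"A": 4})

    def test_weights_sum_to_one_for_every_assignment_up_to_six_items(self):
        """Exhaustive weight-conservation check over all non-null relevance maps."""
        items = ["i1", "i2", "i3", "i4", "i5", "i6"]
        for combo in itertools.product((0, 1, 2, 3), repeat=6):
            if all(r == 0 for r in combo):
                continue
            w = compute_weights(dict(zip(items, combo)))
            assert sum(w.values()) == pytest.approx(1.0, abs=1e-12)
            assert all(w[i] == 0.0 for i, r in zip(items, combo) if r == 0)
            # within-tier equality
            for tier in (1, 2, 3):
                tier_w = [w[i] for i, r in zip(items, combo) if r == tier]
                assert len(set(tier_w)) <= 1


class TestScoreStream:
    def test_weighted_sum_of_ratings(self, make_flat_stream, flat_profile):
        stream = make_flat_stream([{"A": 4, "B": 2, "C": 6}])
        [p] = score_stream(stream, flat_profile)
        assert p.score == pytest.approx(3.8)

    def test_all_minimum_ratings_give_scale_minimum(self, make_flat_stream, flat_profile):
        stream = make_flat_stream([{"A": 1, "B": 1, "C": 1}])
        [p] = score_stream(stream, flat_profile)
        assert p.score == pytest.approx(1.0)

    def test_missed_prompts_yield_no_scores(self, make_flat_stream, flat_profile):
        assert score_stream(make_flat_stream([None, None]), flat_profile) == []

    def test_partial_prompts_excluded_by_default(self, make_flat_stream, flat_profile):
        stream = make_flat_stream([{"A": 4, "B": 2, "C": 6}])
        stream.prompts[0].status = "partial"
        assert score_stream(stream, flat_profile) == []
        assert len(score_stream(stream, flat_profile, include_partial=True)) == 1

    def test_branch_skipped_child_imputed_at_scale_minimum(self, catalogue):
        from .conftest import make_stream

        profile = EWSProfile("p1", {"voices": 3, "voices_distress": 2, "anxious": 1})
        ratings = {it.item_id: 1.0 for it in catalogue.root_items}  # voices at min: child skipped
        stream = make_stream(catalogue, [ratings])
        [p] = score_stream(stream, profile)
        assert p.score == pytest.approx(1.0)

    def test_unanswered_weighted_item_raises_naming_the_prompt(self, make_flat_stream):
        profile = EWSProfile("p1", {"A": 3, "B": 2, "C": 1})
        stream = make_flat_stream([{"A": 4, "B": 2}])
        with pytest.raises(ScoringError, match="2020-01-01"):
            score_stream(stream, profile)

    def test_raising_one_rating_never_decreases_the_score(self, make_flat_stream, flat_profile):
        rng = np.random.default_rng(1)
        for _ in range(100):
            base = {k: int(rng.integers(1, 8)) for k in "ABC"}
            item = "ABC"[rng.integers(3)]
            raised = dict(base)
            raised[item] = min(7, base[item] + int(rng.integers(1, 4)))
            s0 = score_stream(make_flat_stream([base]), flat_profile)[0].score
            s1 = score_stream(make_flat_stream([raised]), flat_profile)[0].score
            assert s1 >= s0 - 1e-12


class TestComputeBaseline:
    def test_mean_over_first_three_days(self):
        pts = points((0.2, 2), (0.8, 2), (1.5, 2), (2.5, 2))
        assert compute_baseline(pts, 3, STUDY_START) == pytest.approx(2.0)

    def test_window_is_calendar_time_not_count(self):
        pts = points((0.5, 1), (2.5, 3), (3.5, 9), (4.0, 9))
        assert compute_baseline(pts, 3, STUDY_START) == pytest.approx(2.0)

    def test_empty_window_is_an_error(self):
        with pytest.raises(InsufficientBaselineError):
            compute_baseline(points((5.0, 2.0)), 3, STUDY_START)


class TestDetectAlerts:
    def test_single_point_rule_fires_at_40_percent_rise(self, flat_profile):
        alerts = detect_alerts(points((4, 2.0), (4.5, 2.9)), 2.0, flat_profile)
        assert len(alerts) == 1
        assert alerts[0].rule == "single_point"
        assert alerts[0].score == pytest.approx(2.9)

    def test_two_consecutive_rule_fires_at_25_percent_pair(self, flat_profile):
        alerts = detect_alerts(points((4, 2.6), (4.25, 2.6)), 2.0, flat_profile)
        assert len(alerts) == 1
        assert alerts[0].rule == "two_consecutive"

    def test_no_alert_when_neither_rule_satisfied(self, flat_profile):
        assert detect_alerts(points((4, 2.6), (4.5, 2.4), (5, 2.6)), 2.0, flat_profile) == []

    def test_refractory_period_suppresses_second_alert(self, flat_profile):
        alerts = detect_alerts(points((4, 2.9), (4.04, 2.9)), 2.0, flat_profile)
        assert len(alerts) == 1

    def test_threshold_attained_with_equality(self, flat_profile):
        # "rose to 40% higher" reads as attainment: 2.8 == 1.4 * 2.0 alerts
        alerts = detect_alerts(points((4, 2.8)), 2.0, flat_profile)
        assert len(alerts) == 1

    def test_consecutive_pair_broken_by_long_gap(self, flat_profile):
        alerts = detect_alerts(points((4, 2.6), (6.5, 2.6)), 2.0, flat_profile)
        assert alerts == []

    def test_single_point_takes_precedence_over_pair_rule(self, flat_profile):
        alerts = detect_alerts(
            points((4, 2.6), (4.5, 2.9)), 2.0, flat_profile, refractory=None
        )
        assert [a.rule for a in alerts] == ["single_point"]

    def test_nonpositive_baseline_rejected(self, flat_profile):
        with pytest.raises(ValueError, match="baseline"):
            detect_alerts(points((4, 2.0)), 0.0, flat_profile)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(deadline=None, derandomize=True, max_examples=30)
    def test_alerts_invariant_to_joint_rescaling(self, scale):
        profile = EWSProfile("p1", {"A": 3, "B": 2, "C": 1})
        pts = points((4, 2.6), (4.5, 2.6), (5, 2.0), (6, 2.9), (7, 3.5))
        base = detect_alerts(pts, 2.0, profile, refractory=None)
        scaled = [ScorePoint(p.prompt_time, p.score * scale) for p in pts]
        rescaled = detect_alerts(scaled, 2.0 * scale, profile, refractory=None)
        assert [(a.alert_time, a.rule) for a in base] == [
            (a.alert_time, a.rule) for a in rescaled
        ]

    def test_lowering_thresholds_never_removes_an_alert(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            pts = points(*((4 + 0.5 * k, float(rng.uniform(1, 4))) for k in range(20)))
            strict = EWSProfile("p1", {"A": 1}, single_point_rise=0.40, consecutive_rise=0.25)
            loose = EWSProfile("p1", {"A": 1}, single_point_rise=0.30, consecutive_rise=0.15)
            a_strict = detect_alerts(pts, 2.0, strict, refractory=None)
            a_loose = detect_alerts(pts, 2.0, loose, refractory=None)
            assert {a.alert_time for a in a_strict} <= {a.alert_time for a in a_loose}


def brute_force_alerts(pts, baseline, profile, max_gap=dt.timedelta(hours=24)):
    """Independent oracle: test every point and every adjacent pair directly."""
    out = []
    for k, p in enumerate(pts):
        if p.score >= baseline * (1 + profile.single_point_rise):
            out.append((p.prompt_time, "single_point"))
        elif (
            k > 0
            and p.score >= baseline * (1 + profile.consecutive_rise)
            and pts[k - 1].score >= baseline * (1 + profile.consecutive_rise)
            and (p.prompt_time - pts[k - 1].prompt_time) <= max_gap
        ):
            out.append((p.prompt_time, "two_consecutive"))
    return out


class TestOracleEquivalence:
    def test_detector_matches_brute_force_on_random_streams(self, flat_profile):
        """Rule application is exactly the pair of inequalities, point by point."""
        rng = np.random.default_rng(123)
        for _ in range(1000):
            n = int(rng.integers(2, 40))
            days = np.cumsum(rng.uniform(0.1, 1.6, n)) + 3.0
            scores = rng.uniform(1.0, 4.0, n)
            pts = points(*zip(days, scores))
            baseline = float(rng.uniform(1.0, 2.5))
            got = detect_alerts(pts, baseline, flat_profile, refractory=None)
            assert [(a.alert_time, a.rule) for a in got] == brute_force_alerts(
                pts, baseline, flat_profile
            )


class TestEWSDetector:
    def test_fit_freezes_weights_and_baseline(self, make_flat_stream):
        stream = make_flat_stream([{"A": 2, "B": 2, "C": 2}] * 6)
        det = EWSDetector(relevance={"A": 3, "B": 2, "C": 1}).fit(stream)
        assert det.baseline_ == pytest.approx(2.0)
        assert det.weights_ == {"A": 0.5, "B": 0.3, "C": 0.2}
        assert det.n_baseline_points_ == 6

    def test_baseline_window_points_never_alert(self, make_flat_stream):
        # a huge spike inside the first 3 days raises the baseline, not an alert
        stream = make_flat_stream([{"A": 7, "B": 7, "C": 7}] + [{"A": 2, "B": 2, "C": 2}] * 9)
        det = EWSDetector(relevance={"A": 3, "B": 2, "C": 1}).fit(stream)
        assert all(a.alert_time >= det.baseline_end_ for a in det.predict(stream))

    def test_predict_alerts_on_post_baseline_rise(self, make_flat_stream):
        maps = [{"A": 2, "B": 2, "C": 2}] * 6 + [{"A": 4, "B": 4, "C": 4}]
        det = EWSDetector(relevance={"A": 3, "B": 2, "C": 1})
        alerts = det.fit_predict(make_flat_stream(maps))
        assert len(alerts) == 1 and alerts[0].rule == "single_point"
        assert alerts[0].baseline == pytest.approx(2.0)

    def test_get_set_params_round_trip(self):
        det = EWSDetector(relevance={"A": 1})
        params = det.get_params()
        assert params["single_point_rise"] == 0.40 and params["baseline_days"] == 3
        det.set_params(consecutive_rise=0.30)
        assert det.consecutive_rise == 0.30
        with pytest.raises(ValueError, match="invalid parameter"):
            det.set_params(nonsense=1)

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        det = EWSDetector(relevance={"A": 2}, refractory_hours=None)
        cloned = clone(det)
        assert cloned.get_params() == det.get_params()

    def test_unfitted_predict_raises(self, make_flat_stream):
        with pytest.raises(RuntimeError, match="not fitted"):
            EWSDetector(relevance={"A": 1}).predict(make_flat_stream([{"A": 1, "B": 1, "C": 1}]))
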