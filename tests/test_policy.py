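"""Alert thresholding, the n-consecutive-alert rule, ROC construction and
policy selection, with brute-force oracles and monotonicity properties."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from ctgrisk.policy import (
    ALERT,
    DEFERRED,
    MISSING,
    NO_ALERT,
    NO_RECOMMEND,
    RECOMMEND,
    DecisionPolicy,
    alert_stream,
    decide_subject,
    recommend,
    roc_for_n,
    select_n,
    select_pt,
    window_scores,
)

A, N, M = ALERT, NO_ALERT, MISSING


class TestAlertStream:
    def test_strict_inequality_at_threshold(self):
        flags = alert_stream(np.array([0.5, 0.5001]), pt=0.5)
        assert list(flags) == [NO_ALERT, ALERT]

    def test_pt_one_never_alerts(self):
        flags = alert_stream(np.array([0.2, 1.0, 0.99]), pt=1.0)
        assert list(flags) == [NO_ALERT] * 3

    def test_pt_zero_alerts_on_any_positive(self):
        flags = alert_stream(np.array([0.01, 0.5, 1.0]), pt=0.0)
        assert list(flags) == [ALERT] * 3

    def test_nan_propagates_as_missing(self):
        flags = alert_stream(np.array([0.9, np.nan, 0.1]), pt=0.5)
        assert list(flags) == [ALERT, MISSING, NO_ALERT]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            alert_stream(np.array([1.2]), pt=0.5)


class TestRecommend:
    def test_five_alerts_recommend_at_fifth_epoch(self):
        """n=5: first possible recommendation after 100 min of monitoring."""
        d = recommend(np.array([A] * 5), DecisionPolicy(n=5, pt=0.5))
        assert d.states == [DEFERRED] * 4 + [RECOMMEND]
        assert d.recommended
        assert d.first_recommendation_epoch == 0  # stream indices 4..0

    def test_one_missing_within_tolerance_still_recommends(self):
        d = recommend(np.array([A, A, M, A, A]), DecisionPolicy(n=5, pt=0.5))
        assert d.states[-1] == RECOMMEND

    def test_three_missing_defers(self):
        d = recommend(np.array([A, M, M, M, A]), DecisionPolicy(n=5, pt=0.5))
        assert d.states[-1] == DEFERRED
        assert not d.recommended

    def test_n_equal_one_recommends_immediately(self):
        d = recommend(np.array([N, A, N]), DecisionPolicy(n=1, pt=0.5))
        assert d.states == [NO_RECOMMEND, RECOMMEND, RECOMMEND]  # latched
        assert d.first_recommendation_epoch == 1

    def test_all_missing_window_is_deferred_even_for_n_one(self):
        d = recommend(np.array([M, M]), DecisionPolicy(n=1, pt=0.5))
        assert d.states == [DEFERRED, DEFERRED]

    def test_latch_keeps_recommending(self):
        d = recommend(np.array([A, A, N, N]), DecisionPolicy(n=2, pt=0.5))
        assert d.states == [DEFERRED, RECOMMEND, RECOMMEND, RECOMMEND]
        assert d.first_recommendation_epoch == 2

    def test_unlatched_rule_can_withdraw(self):
        d = recommend(np.array([A, A, N]), DecisionPolicy(n=2, pt=0.5, latch=False))
        assert d.states == [DEFERRED, RECOMMEND, NO_RECOMMEND]
        assert d.recommended and d.first_recommendation_epoch == 1

    def test_deferral_does_not_reset_run(self):
        # n=2: window [A, M] defers nothing (1 missing <= 1) -> recommend
        d = recommend(np.array([A, M]), DecisionPolicy(n=2, pt=0.5))
        assert d.states == [DEFERRED, RECOMMEND]

    def test_exhaustive_window_truth_table(self):
        """Every window in {alert, no-alert, missing}^n for n=1..10 matches
        the floor(n/2) missing-tolerance rule."""
        for n in range(1, 11):
            policy = DecisionPolicy(n=n, pt=0.5)
            for window in itertools.product((A, N, M), repeat=n):
                d = recommend(np.array(window), policy)
                missing = window.count(M)
                if missing > n // 2 or missing == n:
                    expected = DEFERRED
                elif N in window:
                    expected = NO_RECOMMEND
                else:
                    expected = RECOMMEND
                assert d.states[-1] == expected, (n, window)


class TestWindowScores:
    def test_matches_recommend_on_random_streams(self):
        """s_n > pt iff the state machine recommends, across random data."""
        rng = np.random.default_rng(123)
        for _ in range(300):
            k = int(rng.integers(1, 30))
            phie = rng.random(k)
            phie[rng.random(k) < 0.25] = np.nan
            n = int(rng.integers(1, 11))
            pt = float(rng.random())
            score = window_scores(phie, n)
            d = decide_subject(phie, DecisionPolicy(n=n, pt=pt))
            assert d.recommended == (score > pt)

    def test_no_admissible_window_scores_minus_inf(self):
        assert window_scores(np.array([0.9, 0.9]), n=5) == -np.inf
        assert window_scores(np.array([np.nan, np.nan]), n=1) == -np.inf


class TestRocForN:
    def test_perfect_separation_gives_auc_one(self):
        streams = {f"p{i}": np.ones(6) for i in range(5)}
        streams.update({f"h{i}": np.zeros(6) for i in range(5)})
        labels = {sid: sid.startswith("p") for sid in streams}
        roc = roc_for_n(streams, labels, n=3)
        assert roc.auc == pytest.approx(1.0)

    def test_identical_distributions_give_chance_auc(self):
        rng = np.random.default_rng(99)
        streams = {f"s{i}": rng.random(12) for i in range(400)}
        labels = {f"s{i}": i % 2 == 0 for i in range(400)}
        roc = roc_for_n(streams, labels, n=3)
        assert 0.45 < roc.auc < 0.55

    def test_single_class_rejected(self):
        streams = {"a": np.ones(3), "b": np.ones(3)}
        with pytest.raises(ValueError, match="healthy and pathological"):
            roc_for_n(streams, {"a": True, "b": True}, n=1)

    def test_n1_reduction_matches_bruteforce_threshold_sweep(self):
        """For n=1 the subject score is its max pHIE; enumerate thresholds
        by hand and integrate the ROC directly."""
        rng = np.random.default_rng(5)
        streams = {}
        labels = {}
        for i in range(50):
            k = int(rng.integers(2, 15))
            phie = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=k)  # ties likely
            phie[rng.random(k) < 0.2] = np.nan
            streams[f"s{i}"] = phie
            labels[f"s{i}"] = bool(rng.random() < 0.4)
        if not any(labels.values()) or all(labels.values()):
            labels["s0"] = True
            labels["s1"] = False
        roc = roc_for_n(streams, labels, n=1)

        def max_observed(phie):
            vals = phie[~np.isnan(phie)]
            return vals.max() if len(vals) else -np.inf

        scores = {sid: max_observed(p) for sid, p in streams.items()}
        all_vals = sorted(
            {v for p in streams.values() for v in p[~np.isnan(p)]} | {0.0, 1.0}
        )
        points = [(1.0, 1.0)]
        for pt in all_vals:
            tp = sum(1 for s in streams if labels[s] and scores[s] > pt)
            fp = sum(1 for s in streams if not labels[s] and scores[s] > pt)
            points.append(
                (fp / sum(not v for v in labels.values()),
                 tp / sum(bool(v) for v in labels.values()))
            )
        points.append((0.0, 0.0))
        points = sorted(points)
        want = np.trapezoid([p[1] for p in points], [p[0] for p in points])
        assert roc.auc == pytest.approx(want, abs=1e-12)

    def test_tpr_fpr_monotone_and_auc_bounded(self):
        rng = np.random.default_rng(17)
        streams = {f"s{i}": rng.random(10) for i in range(60)}
        labels = {f"s{i}": i < 20 for i in range(60)}
        for n in (1, 3, 5):
            roc = roc_for_n(streams, labels, n=n)
            assert (np.diff(roc.tpr) <= 1e-12).all()
            assert (np.diff(roc.fpr) <= 1e-12).all()
            assert 0.0 <= roc.auc <= 1.0


class TestMonotonicity:
    def test_raising_pt_never_adds_recommendations(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            phie = rng.random(15)
            phie[rng.random(15) < 0.2] = np.nan
            n = int(rng.integers(1, 8))
            lo, hi = sorted(rng.random(2))
            d_lo = decide_subject(phie, DecisionPolicy(n=n, pt=lo))
            d_hi = decide_subject(phie, DecisionPolicy(n=n, pt=hi))
            assert d_lo.recommended or not d_hi.recommended

    def test_increasing_n_never_adds_recommendations_without_missing(self):
        rng = np.random.default_rng(32)
        for _ in range(100):
            phie = rng.random(15)  # fully observed
            pt = float(rng.random())
            rec = [
                decide_subject(phie, DecisionPolicy(n=n, pt=pt)).recommended
                for n in range(1, 11)
            ]
            assert all(a or not b for a, b in zip(rec, rec[1:]))

    def test_latched_indicator_non_decreasing(self):
        rng = np.random.default_rng(33)
        for _ in range(50):
            phie = rng.random(12)
            d = decide_subject(phie, DecisionPolicy(n=3, pt=0.4))
            seen = [s == RECOMMEND for s in d.states]
            assert all(a <= b for a, b in zip(seen, seen[1:]))


class TestSelectN:
    def test_peak_selected(self):
        aucs = {1: 0.6, 2: 0.65, 3: 0.7, 4: 0.74, 5: 0.78, 6: 0.75, 7: 0.7,
                8: 0.65, 9: 0.6, 10: 0.55}
        assert select_n(aucs) == 5

    def test_ties_break_toward_smaller_n(self):
        assert select_n({n: 0.7 for n in range(1, 11)}) == 1

    def test_single_entry(self):
        assert select_n({4: 0.9}) == 4

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            select_n({})


class TestSelectPt:
    @staticmethod
    def simple_roc():
        streams = {f"h{i}": np.full(4, v) for i, v in enumerate([0.1, 0.4, 0.6, 0.8])}
        streams.update({f"p{i}": np.full(4, 0.9) for i in range(2)})
        labels = {sid: sid.startswith("p") for sid in streams}
        return roc_for_n(streams, labels, n=2)

    def test_target_one_returns_smallest_grid_threshold(self):
        roc = self.simple_roc()
        assert select_pt(roc, 1.0) == roc.thresholds[0]

    def test_unreachable_target_falls_back_to_one_with_warning(self):
        roc = self.simple_roc()
        with pytest.warns(UserWarning, match="pt = 1.0"):
            # every healthy subject scores > pt for all grid pt < max score,
            # except at the top thresholds; force failure with grid trimmed
            trimmed = roc
            trimmed.fpr = np.full_like(roc.fpr, 0.5)
            assert select_pt(trimmed, 0.0) == 1.0

    def test_most_sensitive_admissible_threshold(self):
        roc = self.simple_roc()
        # healthy scores 0.1/0.4/0.6/0.8 -> FPR at pt: 1, .75, .5, .25, 0
        pt = select_pt(roc, target_fpr=0.5)
        assert pt == pytest.approx(0.4)
        below = roc.thresholds[roc.thresholds < pt]
        assert all(
            roc.fpr[np.where(roc.thresholds == b)[0][0]] > 0.5 for b in below
        )
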