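"""Trial taxonomy, session summaries, bouts, criteria, outliers, probes."""

import dataclasses

import numpy as np
import pytest

from timedseq.analysis import (
    MACRON,
    AnalysisError,
    IntegrityError,
    check_criteria,
    classify_trials,
    cumulative_series,
    detect_bouts,
    exclude_outliers,
    probe_measures,
    summarize_session,
    validate_log,
)
from timedseq.config import AdvancementRule, builtin_stage
from timedseq.engine import Press, run_session
from timedseq.logio import Event, SessionSummary

from conftest import scripted_stream


def stream(*steps):
    """steps: (t, lever) pairs."""
    return [Press(t, lever) for t, lever in steps]


class TestClassification:
    @pytest.mark.parametrize(
        "steps, category, canonical",
        [
            ([(1, "L"), (2, "L"), (4, "R"), (5, "R")], "LLRRP", "LLRRP"),
            ([(1, "R")], "R", "R"),
            ([(1, "L"), (2, "R")], "LR", "LR"),
            ([(1, "L"), (2, "L"), (3, "L")], "LLL", "LLL"),
            ([(1, "L"), (1.2, "L")], "LL", "LL_fast2"),
            ([(1, "L"), (7, "L")], "LL" + MACRON, "LL_slow2"),
            ([(1, "L"), (2, "L"), (4, "R"), (4.2, "R")], "LLRR", "LLRR_fast4"),
            ([(1, "L"), (2, "L"), (4, "R"), (10, "R")], "LLRR" + MACRON, "LLRR_slow4"),
            ([(1, "L"), (2, "L"), (4, "R"), (5, "L")], "LLRL", "LLRL"),
            ([(1, "L"), (2, "L"), (2.2, "R")], "LLR", "LLR_fast3"),
        ],
    )
    def test_single_trial_labels(self, baseline, steps, category, canonical):
        log = run_session(baseline, stream(*steps))
        trials = classify_trials(log, baseline)
        assert len(trials) == 1
        assert trials[0].category == category
        assert trials[0].canonical == canonical

    def test_rewarded_iff_correct_on_reinforced_stage(self, baseline):
        log = run_session(baseline, stream((1, "L"), (2, "L"), (4, "R"), (5, "R")))
        (tr,) = classify_trials(log, baseline)
        assert tr.rewarded and tr.completed
        ext = builtin_stage("Extinction")
        log = run_session(ext, stream((1, "L"), (2, "L"), (4, "R"), (5, "R")))
        (tr,) = classify_trials(log, ext)
        assert tr.completed and tr.category == "LLRRP" and not tr.rewarded

    def test_timeout_presses_belong_to_no_trial(self, baseline):
        # error at 1 s, TO presses at 2-4 s, fresh trial from 7 s
        log = run_session(
            baseline,
            stream((1, "R"), (2, "L"), (3, "L"), (7, "L"), (8, "L"), (10, "R"), (11, "R")),
        )
        trials = classify_trials(log, baseline)
        assert [t.category for t in trials] == ["R", "LLRRP"]
        assert sum(len(t.presses) for t in trials) == 5  # 2 TO presses excluded

    def test_tampered_log_raises_integrity_error(self, baseline):
        log = run_session(baseline, stream((1, "L"), (2, "L"), (4, "R"), (5, "R")))
        bad = dataclasses.replace(log)
        i = next(j for j, ev in enumerate(bad.events) if ev.code == 12)
        bad.events = list(bad.events)
        bad.events[i] = Event(ticks=bad.events[i].ticks, code=22)  # flip role
        with pytest.raises(IntegrityError, match="event"):
            validate_log(bad, baseline)


class TestSummarize:
    def test_perfect_session_summary(self, baseline, perfect_baseline_log):
        s = summarize_session(perfect_baseline_log, baseline)
        assert s.rewards == 40 and s.incorrect_presses == 0
        assert s.category_counts == {"LLRRP": 40}
        for st in s.interval_stats.values():
            assert st.n == 40 and st.cv == 0.0 and st.sd == 0.0

    @pytest.mark.parametrize("preset_name", ["control_like", "random"])
    @pytest.mark.parametrize("stage_id", ["LLRR_baseline", "LLRR_alternating", "LR"])
    def test_summary_matches_engine_tallies(self, preset_name, stage_id):
        from timedseq.agents import generate_session, preset

        cfg = builtin_stage(stage_id)
        params = dataclasses.replace(preset(preset_name), seed=11)
        log = run_session(cfg, generate_session(params, cfg))
        s = summarize_session(log, cfg)
        e = log.summary
        assert s.press_counts == e.press_counts
        assert (s.rewards, s.completed_trials, s.trials_attempted) == (
            e.rewards, e.completed_trials, e.trials_attempted,
        )
        assert sum(s.category_counts.values()) == s.trials_attempted

    def test_intervals_only_from_correct_sequences(self, baseline):
        # one error trial with odd gaps, one correct trial with known gaps
        log = run_session(
            baseline,
            stream((1, "L"), (2.9, "L"), (3.2, "R"),  # LLR too fast -> discarded
                   (10, "L"), (11, "L"), (13, "R"), (14, "R")),
        )
        s = summarize_session(log, baseline)
        assert {k: v.mean for k, v in s.interval_stats.items()} == {
            "1:L-L": 1.0, "2:L-R": 2.0, "3:R-R": 1.0,
        }

    def test_cv_is_scale_invariant(self, baseline):
        def session(scale):
            presses, t = [], 0.0
            for gaps in ([0.8, 1.0, 0.9], [1.2, 1.6, 1.1], [1.0, 2.0, 1.3]):
                t += 3.0
                presses.append(Press(t, "L"))
                for lever, g in zip("LRR", gaps):
                    t += g * scale
                    presses.append(Press(t, lever))
            return summarize_session(run_session(baseline, presses), baseline)

        a, b = session(1.0), session(2.0)
        for key in a.interval_stats:
            assert a.interval_stats[key].cv == pytest.approx(
                b.interval_stats[key].cv, abs=1e-9
            )


class TestBouts:
    def test_hand_computed_partition(self, baseline):
        log = run_session(
            baseline, stream((0.01, "L"), (1, "L"), (2, "R"), (100, "L"), (101, "L"))
        )
        bouts, pauses = detect_bouts(log, gap_threshold_s=30)
        assert pauses == [98.0]
        assert bouts == [1.99, 1.0]

    def test_uniform_pressing_has_no_pauses(self, baseline):
        log = run_session(baseline, [Press(1.0 + i, "L") for i in range(20)])
        bouts, pauses = detect_bouts(log, gap_threshold_s=30)
        assert pauses == [] and len(bouts) == 1
        # a tiny threshold splits at every gap
        bouts2, pauses2 = detect_bouts(log, gap_threshold_s=0.5)
        assert len(pauses2) == 19

    def test_partition_and_monotonicity(self, baseline):
        rng = np.random.default_rng(5)
        t, presses = 0.0, []
        for _ in range(100):
            t += float(rng.exponential(8.0))
            presses.append(Press(t, "L"))
        log = run_session(baseline, presses)
        times = [t for t, _, _ in log.presses()]  # tick-quantized
        prev_pauses = None
        for thr in (5.0, 15.0, 45.0):
            bouts, pauses = detect_bouts(log, gap_threshold_s=thr)
            assert sum(bouts) + sum(pauses) == pytest.approx(times[-1] - times[0])
            if prev_pauses is not None:
                assert len(pauses) <= prev_pauses
            prev_pauses = len(pauses)

    def test_degenerate_sessions(self, baseline):
        assert detect_bouts(run_session(baseline, [])) == ([], [])
        assert detect_bouts(run_session(baseline, [Press(1.0, "L")])) == ([0.0], [])


class TestCumulative:
    def test_reward_steps_on_perfect_session(self, baseline, perfect_baseline_log):
        t, c = cumulative_series(perfect_baseline_log, "rewards")
        assert list(c) == list(range(41))
        assert all(np.diff(t) >= 0)

    def test_final_values_match_summary(self, baseline):
        from timedseq.agents import generate_session, preset

        params = dataclasses.replace(preset("control_like"), seed=2)
        log = run_session(baseline, generate_session(params, baseline))
        s = summarize_session(log, baseline)
        for metric, expected in [
            ("rewards", s.rewards),
            ("incorrect_presses", s.incorrect_presses),
            ("timeout_presses", s.timeout_presses),
            ("correct_presses", s.correct_presses),
        ]:
            _, c = cumulative_series(log, metric)
            assert c[-1] == expected

    def test_empty_session_is_constant_zero(self, baseline):
        t, c = cumulative_series(run_session(baseline, []), "rewards")
        assert list(c) == [0]

    def test_unknown_metric_rejected(self, perfect_baseline_log):
        with pytest.raises(AnalysisError, match="unknown metric"):
            cumulative_series(perfect_baseline_log, "pellets")


def S(rewards=0, trials=0):
    return SessionSummary(rewards=rewards, trials_attempted=trials)


class TestCriteria:
    rule_lr = builtin_stage("LR").criteria
    rule_timed = builtin_stage("LLRR_baseline").criteria

    def test_three_consecutive_successes_advance(self):
        hist = [S(40, 40)] * 3
        assert check_criteria(hist, self.rule_lr) == "advance"
        assert check_criteria(hist[:2], self.rule_lr) == "repeat"
        assert check_criteria([S(40), S(12), S(40), S(40)], self.rule_lr) == "repeat"

    def test_exclusion_at_session_cap(self):
        assert check_criteria([S(10, 20)] * 10, self.rule_lr) == "exclude"
        # timed stages rescue animals still doing >= 10 trials
        assert check_criteria([S(10, 8)] * 10, self.rule_timed) == "exclude"
        assert check_criteria([S(10, 12)] * 10, self.rule_timed) == "advance"

    def test_probe_stages_run_fixed_sessions(self):
        rule = builtin_stage("LLRR_middle").criteria
        assert check_criteria([S()], rule) == "repeat"
        assert check_criteria([S()] * 3, rule) == "advance"

    def test_rebaseline_advances_on_first_success(self):
        rule = builtin_stage("LLRR_rebaseline").criteria
        assert check_criteria([S(40, 40)], rule) == "advance"
        assert check_criteria([S(30, 30)], rule) == "repeat"
        assert check_criteria([S(30, 30)] * 3, rule) == "advance"
        assert check_criteria([S(30, 8)] * 3, rule) == "exclude"

    def test_empty_history_rejected(self):
        with pytest.raises(AnalysisError):
            check_criteria([], self.rule_lr)


class TestOutliers:
    def test_far_value_excluded(self):
        kept, idx = exclude_outliers([1] * 9 + [100])
        assert idx == [9] and kept == [1.0] * 9

    def test_constant_list_untouched(self):
        kept, idx = exclude_outliers([3.0, 3.0, 3.0, 3.0])
        assert idx == [] and kept == [3.0] * 4

    def test_values_within_bounds_kept(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        kept, idx = exclude_outliers(vals)
        assert kept == vals and idx == []

    def test_single_pass_not_iterated(self):
        # after removing the extreme value the remainder would flag more;
        # the rule must not recurse
        vals = [0.0] * 8 + [5.0, 50.0]
        kept, idx = exclude_outliers(vals)
        assert idx == [9] and 5.0 in kept

    def test_needs_three_values(self):
        with pytest.raises(AnalysisError):
            exclude_outliers([1.0, 2.0])


class TestProbeMeasures:
    def test_right_probe_counts_premature_fourth_press(self):
        cfg = builtin_stage("LLRR_right")
        log = run_session(cfg, stream((1, "L"), (2, "L"), (4, "R"), (5, "R")))
        pm = probe_measures(log, cfg)
        assert pm["fourth_press_too_fast"] == 1  # 1.0 s < the 1.5 s floor

    def test_middle_probe_counts_third_left_insertion(self):
        cfg = builtin_stage("LLRR_middle")
        log = run_session(cfg, stream((1, "L"), (2, "L"), (4, "L"),
                                      (10, "L"), (11, "L"), (12, "R")))
        pm = probe_measures(log, cfg)
        assert pm["third_press_incorrect_left"] == 1
        assert pm["third_press_too_fast"] == 1  # 1.0 s < the 3 s floor

    def test_extinction_last_interval_per_completed_trial(self):
        from timedseq.agents import generate_session, preset

        cfg = builtin_stage("Extinction")
        log = run_session(cfg, generate_session(preset("perfect"), cfg))
        pm = probe_measures(log, cfg)
        assert pm["completed_trials"] == 40
        assert len(pm["last_interval_s"]) == 40
        assert pm["last_interval_mean"] == pytest.approx(1.2)

    def test_non_probe_stage_rejected(self, baseline, perfect_baseline_log):
        with pytest.raises(AnalysisError, match="not a probe"):
            probe_measures(perfect_baseline_log, baseline)
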