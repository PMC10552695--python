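"""Behavioral parameters computed from session event logs.

Everything here is derived from the event stream alone (press roles per
lever, rewards, time-out markers), independently of the engine's internal
tallies: attempted sequences are partitioned into trials, labeled with the
outcome taxonomy, and summarized into press accounts, interpress-interval
statistics (correct sequences only), coefficient-of-variation measures,
bout/pause structure, cumulative curves, stage-advancement decisions and
the mean ± 2 SD outlier rule.

Trial-outcome labels follow the field's display convention: the emitted
press letters name the trial; a trailing "P" marks a completed correct
sequence (followed by a pellet on reinforced stages); a combining macron
on the final letter marks a too-slow last press.  Thus on an LLRR stage
"LLRRP" is a rewarded trial, "R" started incorrectly with a right press,
"LLL" inserted an incorrect third left, "LL" ended with a too-fast second
press, and "LL̄" with a too-slow one.  A machine-oriented canonical
form ("LL_slow2") accompanies every label.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import LEFT, AdvancementRule, StageConfig
from .engine import Press, run_session
from .logio import (
    Codes,
    IntervalStats,
    SessionLog,
    SessionSummary,
    decode_press,
)

__all__ = [
    "TrialRecord",
    "AnalysisError",
    "IntegrityError",
    "PROBE_STAGES",
    "CUMULATIVE_METRICS",
    "validate_log",
    "classify_trials",
    "summarize_session",
    "detect_bouts",
    "cumulative_series",
    "check_criteria",
    "exclude_outliers",
    "probe_measures",
    "session_table",
    "cumulative_table",
]

MACRON = "̄"

PROBE_STAGES = frozenset(
    {"LLRR_alternating", "LLRR_left", "LLRR_right", "LLRR_middle", "Extinction"}
)


class AnalysisError(ValueError):
    pass


class IntegrityError(AnalysisError):
    """Log events are inconsistent with the stage's contingencies."""


@dataclass
class TrialRecord:
    """One attempted sequence and its outcome."""

    start_t: float
    end_t: float
    presses: list[tuple[str, float, str]]  # (lever, t, role)
    intervals: list[float]
    category: str  # display label, e.g. "LLRRP", "R", "LL̄"
    canonical: str  # machine form, e.g. "LLRRP", "LL_slow2"
    fail_position: int | None
    fail_mode: str | None  # wrong | fast | slow | None
    completed: bool
    rewarded: bool

    @property
    def letters(self) -> str:
        return "".join(lever for lever, _, _ in self.presses)


def _labels(letters: str, mode: str | None, pos: int | None, completed: bool) -> tuple[str, str]:
    if completed:
        return letters + "P", letters + "P"
    if mode == "wrong":
        return letters, letters
    if mode == "fast":
        return letters, f"{letters}_fast{pos}"
    if mode == "slow":
        return letters + MACRON, f"{letters}_slow{pos}"
    return letters + "…", f"{letters}_open"  # session ended mid-trial


_MODE_FROM_ROLE = {"incorrect": "wrong", "too_fast": "fast", "too_slow": "slow"}


def validate_log(log: SessionLog, cfg: StageConfig) -> None:
    """Replay the logged presses through the contingencies and require the
    recomputed event stream to match the logged one exactly.

    Raises ``IntegrityError`` naming the first divergent event.
    """
    if cfg.is_habituation:
        from .engine import run_habituation

        replayed = run_habituation(cfg).events
    else:
        presses = [Press(t=t, lever=lever) for t, lever, _ in log.presses()]
        replayed = run_session(cfg, presses).events
    for i, (a, b) in enumerate(zip(log.events, replayed)):
        if (a.ticks, a.code) != (b.ticks, b.code):
            raise IntegrityError(
                f"event {i}: log has {a.name}@{a.t:.2f}s, "
                f"contingencies give {b.name}@{b.t:.2f}s"
            )
    if len(log.events) != len(replayed):
        raise IntegrityError(
            f"log has {len(log.events)} events, replay gives {len(replayed)}"
        )


def classify_trials(
    log: SessionLog, cfg: StageConfig, validate: bool = True
) -> list[TrialRecord]:
    """Partition the session's presses into labeled trials.

    Every press outside a time-out belongs to exactly one trial; time-out
    presses belong to none.  A trial runs from the first press after
    session start, reward, or time-out expiry to its error press or its
    completing press.
    """
    if validate:
        validate_log(log, cfg)
    if cfg.is_habituation:
        return []  # no lever contingencies, hence no trials
    trials: list[TrialRecord] = []
    cur: list[tuple[str, float, str]] = []

    def finalize(mode: str | None, completed: bool, rewarded: bool) -> None:
        letters = "".join(lever for lever, _, _ in cur)
        pos = len(cur) if mode else None
        category, canonical = _labels(letters, mode, pos, completed)
        times = [t for _, t, _ in cur]
        trials.append(
            TrialRecord(
                start_t=times[0],
                end_t=times[-1],
                presses=list(cur),
                intervals=list(np.diff(times)),
                category=category,
                canonical=canonical,
                fail_position=pos,
                fail_mode=mode,
                completed=completed,
                rewarded=rewarded,
            )
        )
        cur.clear()

    events = log.events
    for idx, ev in enumerate(events):
        rl = decode_press(ev.code)
        if rl is None:
            continue
        role, lever = rl
        if role == "timeout":
            continue
        cur.append((lever, ev.t, role))
        if role == "correct":
            completed = rewarded = False
            for nxt in events[idx + 1 :]:
                if nxt.ticks != ev.ticks or decode_press(nxt.code) is not None:
                    break
                if nxt.code == Codes.TRIAL_COMPLETE:
                    completed = True
                if nxt.code == Codes.REWARD:
                    rewarded = True
            if completed:
                finalize(None, True, rewarded)
        else:
            finalize(_MODE_FROM_ROLE[role], False, False)
    if cur:
        finalize(None, False, False)
    return trials


def summarize_session(
    log: SessionLog,
    cfg: StageConfig,
    gap_threshold_s: float = 30.0,
    validate: bool = True,
) -> SessionSummary:
    """Recompute the full per-session summary from the event stream.

    Interval statistics are computed only over correctly executed
    sequences, per transition, with the sample standard deviation and
    cv = sd / mean.
    """
    trials = classify_trials(log, cfg, validate=validate)
    counts = {
        r: {"L": 0, "R": 0}
        for r in ("correct", "incorrect", "too_fast", "too_slow", "timeout")
    }
    rewards = completed = 0
    duration = 0.0
    for ev in log.events:
        duration = max(duration, ev.t)
        rl = decode_press(ev.code)
        if rl is not None:
            counts[rl[0]][rl[1]] += 1
        elif ev.code == Codes.REWARD:
            rewards += 1
        elif ev.code == Codes.TRIAL_COMPLETE:
            completed += 1

    per_transition: dict[str, list[float]] = {}
    for tr in trials:
        if not tr.completed:
            continue
        for i, gap in enumerate(tr.intervals):
            key = f"{i + 1}:{tr.presses[i][0]}-{tr.presses[i + 1][0]}"
            per_transition.setdefault(key, []).append(gap)
    interval_stats = {}
    for key, gaps in per_transition.items():
        arr = np.asarray(gaps)
        mean = float(arr.mean())
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        interval_stats[key] = IntervalStats(
            n=arr.size, mean=mean, sd=sd, cv=sd / mean if mean > 0 else 0.0
        )

    bouts, pauses = detect_bouts(log, gap_threshold_s=gap_threshold_s)
    summary = SessionSummary(
        stage_id=log.stage_id or cfg.stage_id,
        duration_s=duration,
        rewards=rewards,
        completed_trials=completed,
        trials_attempted=len(trials),
        press_counts=counts,
        category_counts=dict(Counter(tr.category for tr in trials)),
        interval_stats=interval_stats,
        bout_durations=bouts,
        pause_durations=pauses,
    )
    summary.cumulative = {
        m: [(t, c) for t, c in zip(*cumulative_series(log, m))]
        for m in ("rewards", "incorrect_presses", "timeout_presses")
    }
    return summary


def detect_bouts(
    log: SessionLog, gap_threshold_s: float = 30.0
) -> tuple[list[float], list[float]]:
    """Split the session's pressing into activity bouts and pauses.

    A pause is any interpress gap >= ``gap_threshold_s``; bouts are the
    maximal complementary runs of presses.  The durations partition the
    span from the first to the last press (time before the first press is
    not counted).  With a single press the session is one zero-length
    bout; with none, there is no activity to partition.
    """
    if gap_threshold_s <= 0:
        raise AnalysisError("gap_threshold_s must be positive")
    times = [t for t, _, _ in log.presses()]
    if not times:
        return [], []
    if len(times) == 1:
        return [0.0], []
    bouts: list[float] = []
    pauses: list[float] = []
    bout_start = prev = times[0]
    for t in times[1:]:
        gap = t - prev
        if gap >= gap_threshold_s:
            bouts.append(prev - bout_start)
            pauses.append(gap)
            bout_start = t
        prev = t
    bouts.append(prev - bout_start)
    return bouts, pauses


CUMULATIVE_METRICS: dict[str, tuple[int, ...]] = {
    "rewards": (Codes.REWARD,),
    "incorrect_presses": (21, 22, 31, 32, 41, 42),
    "timeout_presses": (51, 52),
    "completed_trials": (Codes.TRIAL_COMPLETE,),
    "correct_presses": (11, 12),
}


def cumulative_series(log: SessionLog, metric: str) -> tuple[np.ndarray, np.ndarray]:
    """Nondecreasing step series (times, counts) for a session metric.

    Starts at (0, 0); the final value equals the corresponding summary
    count.
    """
    try:
        codes = CUMULATIVE_METRICS[metric]
    except KeyError:
        raise AnalysisError(
            f"unknown metric {metric!r}; choose from {sorted(CUMULATIVE_METRICS)}"
        ) from None
    times = [0.0] + [ev.t for ev in log.events if ev.code in codes]
    counts = np.arange(len(times))
    return np.asarray(times), counts


def check_criteria(history: list[SessionSummary], rule: AdvancementRule) -> str:
    """Stage-advancement decision after the sessions in ``history``.

    Returns "advance", "repeat", or "exclude".  Probe stages run a fixed
    session count with no exclusion.  Criterion stages advance after the
    required consecutive successful sessions; at the session cap an animal
    is excluded, unless the stage defines a minimum-trials rescue, in which
    case an animal still attempting at least that many trials on the final
    session is force-advanced.
    """
    if not history:
        raise AnalysisError("history must be nonempty")
    n = len(history)
    if rule.fixed_sessions is not None:
        return "advance" if n >= rule.fixed_sessions else "repeat"

    def success(s: SessionSummary) -> bool:
        if rule.criterion == "rewards":
            return s.rewards >= (rule.required_rewards or 0)
        if rule.criterion == "consume":
            # Pellet consumption is not an observable log event; simulated
            # habituation sessions are taken as criterion-passing.
            return True
        return False

    if n >= rule.consecutive_days and all(
        success(s) for s in history[-rule.consecutive_days :]
    ):
        return "advance"
    if rule.max_sessions is not None and n >= rule.max_sessions:
        if rule.last_session_min_trials is not None:
            if history[-1].trials_attempted >= rule.last_session_min_trials:
                return "advance"
        return "exclude"
    return "repeat"


def exclude_outliers(values) -> tuple[list[float], list[int]]:
    """Single-pass mean ± 2 SD outlier rule (sample SD, n − 1 denominator).

    Values strictly outside the range are flagged; the rule is applied
    once, never iterated.  Returns (kept values, excluded indices).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise AnalysisError("outlier exclusion needs at least 3 values")
    mean = arr.mean()
    sd = arr.std(ddof=1)
    outside = np.abs(arr - mean) > 2 * sd
    kept = [float(v) for v, o in zip(arr, outside) if not o]
    excluded = [int(i) for i in np.flatnonzero(outside)]
    return kept, excluded


def probe_measures(log: SessionLog, cfg: StageConfig, validate: bool = True) -> dict:
    """Stage-appropriate flexibility counters for probe/extinction sessions.

    Alternating and RIGHT probes count premature and delayed fourth
    presses; the LEFT probe counts second-press timing errors; the MIDDLE
    probe counts incorrect third left presses (sequence-structure change)
    and too-fast third presses; Extinction reports the last interpress
    interval of each completed sequence and right-press restarts after
    reward omission.
    """
    if cfg.stage_id not in PROBE_STAGES:
        raise AnalysisError(f"stage {cfg.stage_id} is not a probe/extinction stage")
    trials = classify_trials(log, cfg, validate=validate)

    def n_fail(mode: str, pos: int) -> int:
        return sum(
            1 for t in trials if t.fail_mode == mode and t.fail_position == pos
        )

    def restarts_after(pred) -> int:
        n = 0
        for prev, t in zip(trials, trials[1:]):
            if pred(prev) and t.fail_mode == "wrong" and t.fail_position == 1 and t.letters == "R":
                n += 1
        return n

    if cfg.stage_id == "LLRR_alternating":
        return {
            "fourth_press_too_fast": n_fail("fast", 4),
            "fourth_press_too_slow": n_fail("slow", 4),
            "post_reward_right_starts": restarts_after(
                lambda p: p.completed and len(p.presses) == 3
            ),
        }
    if cfg.stage_id == "LLRR_left":
        return {
            "second_press_too_fast": n_fail("fast", 2),
            "second_press_too_slow": n_fail("slow", 2),
        }
    if cfg.stage_id == "LLRR_right":
        return {
            "fourth_press_too_fast": n_fail("fast", 4),
            "fourth_press_too_slow": n_fail("slow", 4),
        }
    if cfg.stage_id == "LLRR_middle":
        return {
            "third_press_incorrect_left": sum(
                1
                for t in trials
                if t.fail_mode == "wrong"
                and t.fail_position == 3
                and t.presses[2][0] == LEFT
            ),
            "third_press_too_fast": n_fail("fast", 3),
        }
    # Extinction
    last_intervals = [t.intervals[-1] for t in trials if t.completed and t.intervals]
    return {
        "completed_trials": sum(t.completed for t in trials),
        "last_interval_s": last_intervals,
        "last_interval_mean": float(np.mean(last_intervals)) if last_intervals else float("nan"),
        "post_omission_right_starts": restarts_after(lambda p: p.completed),
    }


# ---------------------------------------------------------------------------
# Tabular exports
# ---------------------------------------------------------------------------


def session_table(
    summaries: list[SessionSummary], meta: list[dict] | None = None
) -> pd.DataFrame:
    """Flat per-session parameter table (one row per session)."""
    rows = []
    for i, s in enumerate(summaries):
        row = dict(meta[i]) if meta else {}
        row.update(s.to_flat())
        rows.append(row)
    return pd.DataFrame(rows)


def cumulative_table(log: SessionLog, metrics: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Long-format cumulative step series for a session."""
    metrics = metrics or tuple(CUMULATIVE_METRICS)
    frames = []
    for m in metrics:
        t, c = cumulative_series(log, m)
        frames.append(pd.DataFrame({"metric": m, "time_s": t, "count": c}))
    return pd.concat(frames, ignore_index=True)
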