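"""Event-driven contingency engine for the timed sequence task.

Given a stage configuration and a time-ordered stream of lever presses,
the engine reproduces the operant box's behavior exactly: it advances or
resets the press sequence, checks each interpress interval against its
closed timing window, schedules the 5 s time-out after every pressing or
timing error, delivers rewards on completed correct sequences (unless the
stage is extinction), drives the cue lights, and terminates the session at
the reward cap, the trial cap, or the time cap — whichever comes first.

All times are quantized to 0.01 s clock ticks at ingest.  Lateness is
evaluated at press time: a limit overrun only becomes an error when the
late press actually arrives, so a trial with no further presses simply
never completes (the log dialect records presses and deliveries, not
silent deadline expiries).
"""

from __future__ import annotations

from dataclasses import dataclass

from .config import LEFT, RIGHT, StageConfig
from .logio import (
    Codes,
    Event,
    SessionLog,
    SessionSummary,
    TICK_S,
    press_code,
    to_ticks,
)

__all__ = [
    "Press",
    "PressOutcome",
    "SessionState",
    "SessionRunner",
    "EngineError",
    "SessionEndedError",
    "handle_press",
    "run_session",
    "run_habituation",
    "alternation_target",
]


class EngineError(ValueError):
    pass


class SessionEndedError(EngineError):
    """A press arrived after session termination (out-of-session)."""


@dataclass(frozen=True)
class Press:
    """One lever press: time in seconds from session start, lever L/R."""

    t: float
    lever: str

    def __post_init__(self) -> None:
        if self.t < 0:
            raise EngineError("press time must be nonnegative")
        if self.lever not in (LEFT, RIGHT):
            raise EngineError(f"lever must be L or R, got {self.lever!r}")


@dataclass(frozen=True)
class PressOutcome:
    """Role assigned to one press by the contingencies."""

    role: str  # correct | incorrect | too_fast | too_slow | timeout
    lever: str
    t: float
    trial_completed: bool = False
    rewarded: bool = False


@dataclass
class SessionState:
    """Mutable engine state; exposed read-only to agents and analyzers."""

    active_sequence: tuple[str, ...]
    position: int = 0
    last_press_ticks: int | None = None
    timeout_until_ticks: int | None = None
    rewards: int = 0
    completed_trials: int = 0
    trials_attempted: int = 0
    elapsed_ticks: int = 0
    ended: bool = False
    end_reason: str = ""

    @property
    def in_timeout(self) -> bool:
        return self.timeout_until_ticks is not None

    @property
    def elapsed(self) -> float:
        return self.elapsed_ticks * TICK_S


def alternation_target(completed_trials: int, cfg: StageConfig) -> tuple[str, ...]:
    """Target sequence for the trial following ``completed_trials`` rewards.

    With period p, every p-th completed trial requires the alternate
    (shortened) sequence; failed attempts do not advance the schedule.
    """
    if cfg.alternation is None:
        raise EngineError(f"stage {cfg.stage_id} has no alternation rule")
    if (completed_trials + 1) % cfg.alternation.period == 0:
        return cfg.alternation.alternate_sequence
    return cfg.target_sequence


class SessionRunner:
    """Replays presses against a stage's contingencies, emitting events."""

    def __init__(self, cfg: StageConfig):
        if cfg.is_habituation:
            raise EngineError(
                f"stage {cfg.stage_id} is a habituation stage; use run_habituation"
            )
        self.cfg = cfg
        self._counts: dict[str, dict[str, int]] = {
            r: {LEFT: 0, RIGHT: 0}
            for r in ("correct", "incorrect", "too_fast", "too_slow", "timeout")
        }
        self.cap_ticks = to_ticks(cfg.session_cap_s)
        self.timeout_ticks = to_ticks(cfg.timeout_s)
        self._window_ticks = [(to_ticks(w.low), to_ticks(w.high)) for w in cfg.windows]
        self.state = SessionState(active_sequence=self._target(0))
        self.events: list[Event] = []
        self._armed: tuple[str, ...] = ()
        self._emit(0, Codes.SESSION_START)
        self._arm(0)

    # -- internals ---------------------------------------------------------

    def _target(self, completed: int) -> tuple[str, ...]:
        if self.cfg.alternation is not None:
            return alternation_target(completed, self.cfg)
        return self.cfg.target_sequence

    def _emit(self, ticks: int, code: int) -> None:
        self.events.append(Event(ticks=ticks, code=code))

    def _arm(self, ticks: int) -> None:
        """Turn on the cue(s) for the currently expected lever(s)."""
        levers = (LEFT, RIGHT) if self.cfg.any_lever else (
            self.state.active_sequence[self.state.position],
        )
        for lever in levers:
            self._emit(ticks, Codes.CUE_ON_L if lever == LEFT else Codes.CUE_ON_R)
        self._armed = levers

    def _disarm(self, ticks: int) -> None:
        for lever in self._armed:
            self._emit(ticks, Codes.CUE_OFF_L if lever == LEFT else Codes.CUE_OFF_R)
        self._armed = ()

    def _flush_timeout(self, ticks: int) -> None:
        """Emit the pending time-out offset once its expiry has passed."""
        until = self.state.timeout_until_ticks
        if until is not None and ticks >= until:
            self._emit(until, Codes.TIMEOUT_OFFSET)
            self.state.timeout_until_ticks = None
            self._arm(until)

    def _tally(self, role: str, lever: str) -> None:
        self._counts[role][lever] += 1

    # -- public API --------------------------------------------------------

    def step(self, press: Press) -> PressOutcome:
        """Apply one press to the contingencies; returns its outcome.

        Raises ``SessionEndedError`` for presses at or after session end.
        """
        st = self.state
        ticks = to_ticks(press.t)
        if st.ended or ticks >= self.cap_ticks:
            raise SessionEndedError(
                f"press at {press.t:.2f}s is outside the session"
            )
        if ticks < st.elapsed_ticks:
            raise EngineError("press stream is not time-ordered")

        # Press inside an active time-out: tallied per lever, sequence
        # position unchanged, the lockout is NOT extended.
        if st.timeout_until_ticks is not None and ticks < st.timeout_until_ticks:
            self._emit(ticks, press_code("timeout", press.lever))
            self._tally("timeout", press.lever)
            st.elapsed_ticks = ticks
            return PressOutcome(role="timeout", lever=press.lever, t=press.t)
        self._flush_timeout(ticks)

        if st.position == 0:
            st.trials_attempted += 1

        role = "correct"
        expected = st.active_sequence[st.position]
        if not self.cfg.any_lever and press.lever != expected:
            role = "incorrect"
        elif st.position > 0:
            low, high = self._window_ticks[st.position - 1]
            gap = ticks - (st.last_press_ticks or 0)
            if gap < low:
                role = "too_fast"
            elif gap > high:
                role = "too_slow"

        self._emit(ticks, press_code(role, press.lever))
        self._tally(role, press.lever)
        st.elapsed_ticks = ticks

        if role != "correct":
            # Error: sequence resets, cue lights off, 5 s lockout begins.
            st.position = 0
            st.last_press_ticks = None
            self._disarm(ticks)
            if self.timeout_ticks > 0:
                st.timeout_until_ticks = ticks + self.timeout_ticks
                self._emit(ticks, Codes.TIMEOUT_ONSET)
            else:
                self._arm(ticks)
            return PressOutcome(role=role, lever=press.lever, t=press.t)

        st.position += 1
        st.last_press_ticks = ticks
        completed = st.position == len(st.active_sequence)
        rewarded = False
        self._disarm(ticks)
        if completed:
            st.completed_trials += 1
            self._emit(ticks, Codes.TRIAL_COMPLETE)
            if self.cfg.reinforced:
                st.rewards += 1
                rewarded = True
                self._emit(ticks, Codes.REWARD)
            # Re-arm the (possibly alternated) sequence from the start.
            st.position = 0
            st.last_press_ticks = None
            st.active_sequence = self._target(st.completed_trials)
            if st.rewards >= self.cfg.reward_cap:
                self.finalize(ticks, "reward_cap")
            elif self.cfg.trial_cap is not None and st.completed_trials >= self.cfg.trial_cap:
                self.finalize(ticks, "trial_cap")
            else:
                self._arm(ticks)
        else:
            self._arm(ticks)
        return PressOutcome(
            role="correct",
            lever=press.lever,
            t=press.t,
            trial_completed=completed,
            rewarded=rewarded,
        )

    def finalize(self, end_ticks: int | None = None, reason: str = "time_cap") -> None:
        """Terminate the session, flushing any pending time-out offset."""
        if self.state.ended:
            return
        if end_ticks is None:
            end_ticks = self.cap_ticks
        self._flush_timeout(end_ticks)
        self._disarm(end_ticks)
        self._emit(end_ticks, Codes.SESSION_END)
        self.state.elapsed_ticks = end_ticks
        self.state.ended = True
        self.state.end_reason = reason

    def summary(self) -> SessionSummary:
        """Summary built from the engine's own tallies."""
        st = self.state
        return SessionSummary(
            stage_id=self.cfg.stage_id,
            duration_s=st.elapsed_ticks * TICK_S,
            rewards=st.rewards,
            completed_trials=st.completed_trials,
            trials_attempted=st.trials_attempted,
            press_counts={r: dict(c) for r, c in self._counts.items()},
        )


def handle_press(runner: SessionRunner, press: Press) -> tuple[SessionRunner, PressOutcome, list[Event]]:
    """Functional wrapper over ``SessionRunner.step``.

    Returns the (mutated) runner, the press outcome, and the events this
    press caused to be emitted.
    """
    n0 = len(runner.events)
    outcome = runner.step(press)
    return runner, outcome, runner.events[n0:]


def _make_log(
    cfg: StageConfig,
    events: list[Event],
    summary: SessionSummary,
    header: dict[str, str] | None,
) -> SessionLog:
    h = dict(header or {})
    h.setdefault("stage", cfg.stage_id)
    h.setdefault("config", cfg.fingerprint())
    return SessionLog(header=h, events=events, summary=summary)


def run_session(
    cfg: StageConfig,
    presses,
    header: dict[str, str] | None = None,
) -> SessionLog:
    """Replay a press stream to termination and return the session log.

    The stream is truncated at session end: at the reward cap (or, on an
    unreinforced stage, the trial cap) the session ends at that press; an
    exhausted stream ends the session at the time cap.
    """
    runner = SessionRunner(cfg)
    last = -1
    for press in presses:
        ticks = to_ticks(press.t)
        if ticks < last:
            raise EngineError("press stream is not time-ordered")
        last = ticks
        if runner.state.ended or ticks >= runner.cap_ticks:
            break
        runner.step(press)
    runner.finalize()
    return _make_log(cfg, runner.events, runner.summary(), header)


def run_habituation(cfg: StageConfig, header: dict[str, str] | None = None) -> SessionLog:
    """Simulate a habituation session (scheduled deliveries only).

    Emits the manual pellet preload (if any) at session start and one
    reward-delivery event per scheduled period until the session cap.
    """
    if not cfg.is_habituation:
        raise EngineError(f"stage {cfg.stage_id} is not a habituation stage")
    cap = to_ticks(cfg.session_cap_s)
    events = [Event(ticks=0, code=Codes.SESSION_START)]
    events += [Event(ticks=0, code=Codes.PELLET_PRELOAD)] * cfg.manual_preload
    rewards = 0
    if cfg.scheduled_delivery_s is not None:
        period = to_ticks(cfg.scheduled_delivery_s)
        t = period
        while t <= cap and rewards < cfg.reward_cap:
            events.append(Event(ticks=t, code=Codes.REWARD))
            rewards += 1
            t += period
    events.append(Event(ticks=cap, code=Codes.SESSION_END))
    summary = SessionSummary(
        stage_id=cfg.stage_id, duration_s=cfg.session_cap_s, rewards=rewards
    )
    return _make_log(cfg, events, summary, header)
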