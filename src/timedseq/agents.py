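"""Parameterized synthetic mouse policies.

An agent is a stationary per-stage policy that emits a time-ordered press
stream for any stage configuration.  Interpress intervals on trained
transitions are log-normal (positive support, right-skewed interresponse
times); wrong-lever, premature and late presses are injected at stated
probabilities; activity alternates bouts and pauses via a two-state
renewal process with exponential dwell times; during time-outs the agent
presses at a Poisson rate.  Flexibility is captured by a single
``perseveration`` probability: on each transition the agent samples either
from its trained (pre-change) timing policy or from a window-adapted
policy whose median is the trained median clipped into the current stage's
window.  Perseveration also drives sequence-level habits: completing the
full trained sequence after an alternate (shortened) trial's reward, and
maintaining (rather than restarting) behavior when reward is omitted.

The agent co-simulates the contingencies with its own engine instance, so
its reactions (time-out pressing, sequence restarts) are exactly
consistent with what the engine will decide when the stream is replayed.

Two cohort presets, ``control_like`` and ``vpa_like``, differ only in
documented directions: the vpa-like phenotype has longer interpress
medians, a lower time-out press rate, and higher perseveration.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .analysis import check_criteria, summarize_session
from .config import LEFT, RIGHT, StageConfig, TimeWindow, canonical_protocol
from .engine import Press, SessionRunner, run_habituation, run_session
from .logio import SessionLog, SessionSummary, TICK_S, to_ticks

__all__ = [
    "AgentParams",
    "AgentError",
    "preset",
    "PRESET_NAMES",
    "generate_session",
    "simulate_cohort",
    "AnimalRecord",
    "SessionRecord",
]

_N_TRANSITIONS = 3  # longest builtin sequence (LLRR) has three transitions


class AgentError(ValueError):
    pass


def _as_mu_tuple(x) -> tuple[float, ...]:
    if isinstance(x, (int, float)):
        return (float(x),) * _N_TRANSITIONS
    return tuple(float(v) for v in x)


@dataclass(frozen=True)
class AgentParams:
    """Parameter set of one synthetic mouse policy.

    interval_mu:
        log-scale location of the trained log-normal interpress interval,
        per transition (scalar broadcasts); the trained median is
        ``exp(interval_mu)`` seconds.
    interval_sigma:
        log-scale spread; 0 collapses timing to the (window-adapted)
        median exactly.
    lever_confusion_p, premature_p, late_p:
        per-press probabilities of the wrong lever, a deliberately early
        press, and a deliberately late press (late injection is skipped on
        effectively untimed transitions).
    timeout_press_rate:
        presses per second emitted during time-outs (Poisson).
    bout_mean_s, pause_mean_s, pause_p:
        two-state renewal activity process — exponential bout and pause
        dwell means, plus an extra per-trial-boundary pause probability.
    perseveration:
        probability of sampling timing/sequence from the trained policy
        after a contingency change instead of the window-adapted one.
    """

    interval_mu: tuple[float, ...] | float = math.log(1.2)
    interval_sigma: float = 0.3
    lever_confusion_p: float = 0.05
    premature_p: float = 0.05
    late_p: float = 0.02
    timeout_press_rate: float = 0.5
    bout_mean_s: float = 180.0
    pause_mean_s: float = 45.0
    pause_p: float = 0.05
    perseveration: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "interval_mu", _as_mu_tuple(self.interval_mu))
        for name in ("lever_confusion_p", "premature_p", "late_p", "pause_p", "perseveration"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise AgentError(f"{name} must be in [0, 1], got {v}")
        if self.interval_sigma < 0 or self.timeout_press_rate < 0:
            raise AgentError("spread and rates must be nonnegative")
        if self.bout_mean_s <= 0 or self.pause_mean_s <= 0:
            raise AgentError("bout/pause means must be positive")

    def trained_median(self, transition: int) -> float:
        mu = self.interval_mu[min(transition, len(self.interval_mu) - 1)]
        return math.exp(mu)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_CONTROL = AgentParams(
    interval_mu=(math.log(1.2), math.log(1.2), math.log(0.9)),
    interval_sigma=0.35,
    lever_confusion_p=0.06,
    premature_p=0.08,
    late_p=0.02,
    timeout_press_rate=0.8,
    bout_mean_s=150.0,
    pause_mean_s=45.0,
    pause_p=0.08,
    perseveration=0.15,
)

_PRESETS: dict[str, AgentParams] = {
    "perfect": AgentParams(
        interval_mu=math.log(1.2),
        interval_sigma=0.0,
        lever_confusion_p=0.0,
        premature_p=0.0,
        late_p=0.0,
        timeout_press_rate=0.0,
        bout_mean_s=1e6,
        pause_mean_s=1.0,
        pause_p=0.0,
        perseveration=0.0,
    ),
    "random": AgentParams(
        interval_mu=math.log(2.0),
        interval_sigma=1.0,
        lever_confusion_p=0.5,
        premature_p=0.0,
        late_p=0.0,
        timeout_press_rate=0.5,
        bout_mean_s=120.0,
        pause_mean_s=60.0,
        pause_p=0.1,
        perseveration=0.0,
    ),
    "control_like": _CONTROL,
    # vpa_like differs from control_like ONLY in the documented phenotype
    # directions: longer interpress medians, fewer time-out presses,
    # stronger perseveration.
    "vpa_like": dataclasses.replace(
        _CONTROL,
        interval_mu=(math.log(1.5), math.log(1.5), math.log(1.15)),
        timeout_press_rate=0.35,
        perseveration=0.45,
    ),
}

PRESET_NAMES = tuple(_PRESETS)


def preset(name: str) -> AgentParams:
    """Named agent preset: perfect, random, control_like, or vpa_like."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise AgentError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESET_NAMES)}"
        ) from None


# ---------------------------------------------------------------------------
# Session generation
# ---------------------------------------------------------------------------


def _adapted_median(window: TimeWindow, trained: float) -> float:
    """Trained median minimally shifted into the current window."""
    lo, hi = 1.15 * window.low, 0.85 * window.high
    if lo > hi:
        return math.sqrt(window.low * window.high)
    return min(max(trained, lo), hi)


class _Agent:
    def __init__(self, params: AgentParams, cfg: StageConfig):
        self.p = params
        self.cfg = cfg
        self.rng = np.random.default_rng(params.seed)
        self.runner = SessionRunner(cfg)
        self.presses: list[Press] = []
        self.last_ticks = 0
        self.active_s = 0.0  # pressing time since the last pause
        self.bout_len = self.rng.exponential(params.bout_mean_s)

    # -- low level ---------------------------------------------------------

    def feed(self, ticks: int, lever: str):
        """Send one press to the co-simulated engine; None once the session
        is over."""
        ticks = max(ticks, self.last_ticks)  # keep the stream time-ordered
        if self.runner.state.ended or ticks >= self.runner.cap_ticks:
            return None
        press = Press(t=ticks * TICK_S, lever=lever)
        out = self.runner.step(press)
        self.presses.append(press)
        self.last_ticks = ticks
        return out

    def choose_lever(self, target: str) -> str:
        if self.rng.random() < self.p.lever_confusion_p:
            return RIGHT if target == LEFT else LEFT
        return target

    def sample_gap(self, transition: int) -> float:
        """Interpress interval for one transition of the active sequence."""
        w = self.cfg.windows[transition]
        trained = self.p.trained_median(transition)
        u = self.rng.random()
        if u < self.p.premature_p and w.low > TICK_S:
            return w.low * self.rng.uniform(0.2, 0.9)
        if u < self.p.premature_p + self.p.late_p and w.high <= 600:
            return w.high * self.rng.uniform(1.05, 1.5)
        median = (
            trained
            if self.rng.random() < self.p.perseveration
            else _adapted_median(w, trained)
        )
        if not self.cfg.reinforced and transition == len(self.cfg.windows) - 1:
            # Reward omission: perseverative animals respond by stretching
            # the final interval rather than restructuring the sequence.
            median *= 1.0 + 0.35 * self.p.perseveration
        if self.p.interval_sigma == 0:
            return median
        return float(self.rng.lognormal(math.log(median), self.p.interval_sigma))

    def timeout_presses(self, err_ticks: int) -> None:
        """Poisson pressing strictly inside the lockout that follows an error."""
        until = self.runner.state.timeout_until_ticks
        if until is None or until - err_ticks <= 2 or self.p.timeout_press_rate == 0:
            return
        n = self.rng.poisson(self.p.timeout_press_rate * (until - err_ticks) * TICK_S)
        if n == 0:
            return
        ticks = np.sort(
            np.unique(self.rng.integers(err_ticks + 1, until, size=n))
        )
        for t in ticks:
            lever = LEFT if self.rng.random() < 0.5 else RIGHT
            if self.feed(int(t), lever) is None:
                return

    def resume_time(self) -> float:
        """Earliest time the agent will act after an error (lockout expiry)."""
        until = self.runner.state.timeout_until_ticks
        if until is not None:
            return until * TICK_S
        return self.last_ticks * TICK_S

    def maybe_pause(self) -> float:
        extra = self.rng.random() < self.p.pause_p
        if self.active_s > self.bout_len or extra:
            self.active_s = 0.0
            self.bout_len = self.rng.exponential(self.p.bout_mean_s)
            return float(self.rng.exponential(self.p.pause_mean_s))
        return 0.0

    def start_latency(self) -> float:
        if self.p.interval_sigma == 0:
            return 2.0
        return float(self.rng.lognormal(math.log(2.0), 0.4))

    # -- main loop ---------------------------------------------------------

    def run(self) -> list[Press]:
        state = self.runner.state
        cursor = 0.0
        while not state.ended:
            cursor += self.maybe_pause() + self.start_latency()
            trial_start = cursor
            seq = state.active_sequence
            t = cursor
            for k, target in enumerate(seq):
                if k > 0:
                    gap = self.sample_gap(k - 1)
                    # Bridging press: while waiting out a gap much longer
                    # than trained, non-perseverative animals are prone to
                    # re-press the lever they are on (a sequence-structure
                    # error, e.g. an extra third left in the MIDDLE probe).
                    # Only error-prone policies (nonzero lever confusion)
                    # improvise like this.
                    prev = seq[k - 1]
                    if (
                        prev != target
                        and self.p.lever_confusion_p > 0
                        and gap > 2 * self.p.trained_median(k - 1)
                        and self.rng.random() < 0.5 * (1 - self.p.perseveration)
                    ):
                        bridge = self.feed(to_ticks(t + gap * 0.5), prev)
                        if bridge is None:
                            return self.presses
                        self._after_error(bridge)
                        cursor = self.resume_time()
                        break
                    t += gap
                out = self.feed(to_ticks(t), self.choose_lever(target))
                if out is None:
                    return self.presses
                t = self.last_ticks * TICK_S
                if out.role != "correct":
                    self._after_error(out)
                    cursor = self.resume_time()
                    break
                if out.trial_completed:
                    cursor = t
                    self._maybe_habit_press(seq)
                    cursor = max(cursor, self.last_ticks * TICK_S)
                    break
            else:
                cursor = t
            self.active_s += max(cursor, t) - trial_start
        return self.presses

    def _after_error(self, _outcome) -> None:
        if self.runner.state.ended:
            return
        if self.runner.state.in_timeout:
            self.timeout_presses(self.last_ticks)

    def _maybe_habit_press(self, seq: tuple[str, ...]) -> None:
        """Stereotypical completion of the trained sequence after an
        alternate (shortened) trial's reward: the omitted press is emitted
        anyway and falls under the next trial's contingency."""
        base = self.cfg.target_sequence
        if len(seq) >= len(base):
            return
        if self.rng.random() >= self.p.perseveration:
            return
        gap = self.sample_gap(len(seq) - 1)
        out = self.feed(to_ticks(self.last_ticks * TICK_S + gap), base[len(seq)])
        if out is not None and out.role != "correct":
            self._after_error(out)


def generate_session(params: AgentParams, cfg: StageConfig) -> list[Press]:
    """Generate one session's press stream for an agent on a stage.

    The stream is deterministic given (params, cfg) and runs until the
    co-simulated session terminates (reward cap, trial cap, or time cap).
    Habituation stages involve no pressing and yield an empty stream.
    """
    if cfg.is_habituation:
        return []
    return _Agent(params, cfg).run()


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class SessionRecord:
    stage_id: str
    session_index: int
    log: SessionLog
    summary: SessionSummary
    decision: str


@dataclass
class AnimalRecord:
    animal_id: str
    preset_name: str
    sessions: list[SessionRecord] = field(default_factory=list)
    excluded_at: str | None = None

    def stage_sessions(self, stage_id: str) -> list[SessionRecord]:
        return [s for s in self.sessions if s.stage_id == stage_id]


_MAX_SESSIONS_GUARD = 30


def simulate_cohort(
    presets,
    n_per_group: int,
    protocol: list[StageConfig] | None = None,
    seed: int = 0,
) -> list[AnimalRecord]:
    """Simulate a cohort through the full stage progression.

    ``presets`` is a list of preset names or AgentParams (one per group);
    each of the ``n_per_group`` animals per group gets a deterministic
    per-animal seed derived from the master seed.  Advancement, repetition
    and exclusion between stages follow each stage's criteria, mirroring
    the study flow.
    """
    if n_per_group < 1:
        raise AgentError("n_per_group must be >= 1")
    protocol = protocol if protocol is not None else canonical_protocol()
    animals: list[AnimalRecord] = []
    for gi, p in enumerate(presets):
        name = p if isinstance(p, str) else getattr(p, "name", f"group{gi}")
        base = preset(p) if isinstance(p, str) else p
        for ai in range(n_per_group):
            ss = np.random.SeedSequence(entropy=seed, spawn_key=(gi, ai))
            seeder = np.random.default_rng(ss)
            record = AnimalRecord(animal_id=f"{name}_{ai:02d}", preset_name=name)
            for cfg in protocol:
                history: list[SessionSummary] = []
                decision = "repeat"
                while decision == "repeat" and len(history) < _MAX_SESSIONS_GUARD:
                    header = {
                        "animal": record.animal_id,
                        "stage": cfg.stage_id,
                        "session": str(len(history) + 1),
                        "date": "synthetic",
                    }
                    if cfg.is_habituation:
                        log = run_habituation(cfg, header)
                    else:
                        params = dataclasses.replace(
                            base, seed=int(seeder.integers(2**31))
                        )
                        log = run_session(cfg, generate_session(params, cfg), header)
                    summary = summarize_session(log, cfg, validate=False)
                    history.append(summary)
                    decision = check_criteria(history, cfg.criteria)
                    record.sessions.append(
                        SessionRecord(
                            stage_id=cfg.stage_id,
                            session_index=len(history),
                            log=log,
                            summary=summary,
                            decision=decision,
                        )
                    )
                if decision == "exclude":
                    record.excluded_at = cfg.stage_id
                    break
            animals.append(record)
    return animals
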