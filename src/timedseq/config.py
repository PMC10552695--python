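"""Stage configurations for the timed lever-press sequence task.

The task is a multi-stage operant paradigm: after habituation and basic
operant training, mice acquire a four-press LLRR lever sequence in which
every interpress interval must fall inside a predefined time window, and
are then challenged with probe stages that alter the sequence (alternating
LLRR/LLR) or the windows (LEFT / RIGHT / MIDDLE), ending with extinction.
This module encodes every stage's contingencies — target sequence, timing
windows, time-out, session caps, reinforcement, alternation rule, and
advancement/exclusion criteria — as validated, serializable configuration
objects, and ships the canonical 15-stage protocol as machine-readable
defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import yaml

__all__ = [
    "LEFT",
    "RIGHT",
    "UNTIMED",
    "STAGE_ORDER",
    "TimeWindow",
    "Alternation",
    "AdvancementRule",
    "StageConfig",
    "ConfigError",
    "ProtocolError",
    "builtin_stage",
    "canonical_protocol",
    "load_protocol",
    "save_protocol",
    "bundled_protocol_path",
]

LEFT = "L"
RIGHT = "R"

#: Sentinel window for untimed transitions: the acquisition-software scale
#: uses 0.05 s as the shortest resolvable interval and 3600 s (a full
#: session) as "no upper limit".
UNTIMED_LOW = 0.05
UNTIMED_HIGH = 3600.0


class ConfigError(ValueError):
    """A stage configuration violates an invariant."""


class ProtocolError(ValueError):
    """A protocol document failed to parse or validate."""


@dataclass(frozen=True)
class TimeWindow:
    """Closed interval [low, high] of legal interpress intervals, seconds.

    Both bounds are inclusive: an interval exactly equal to ``low`` or
    ``high`` is correct, so the printed window edges themselves are legal.
    """

    low: float
    high: float

    def __post_init__(self) -> None:
        if not (0 <= self.low <= self.high):
            raise ConfigError(f"invalid window: need 0 <= low <= high, got {self}")

    @property
    def untimed(self) -> bool:
        return self.low == UNTIMED_LOW and self.high == UNTIMED_HIGH

    def as_pair(self) -> list[float]:
        return [self.low, self.high]


UNTIMED = TimeWindow(UNTIMED_LOW, UNTIMED_HIGH)


@dataclass(frozen=True)
class Alternation:
    """Every ``period``-th completed trial requires ``alternate_sequence``."""

    period: int
    alternate_sequence: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.period < 2:
            raise ConfigError("alternation period must be >= 2")
        if not all(s in (LEFT, RIGHT) for s in self.alternate_sequence):
            raise ConfigError("alternate_sequence must contain only L/R")


@dataclass(frozen=True)
class AdvancementRule:
    """Per-stage advancement and exclusion criteria.

    criterion:
        "rewards"   — a session is successful when it earns ``required_rewards``;
        "consume"   — success means all pellets were consumed (assumed true in
                      simulation, where consumption is not an observable event);
        "none"      — no per-session criterion (probe stages run a fixed count).
    consecutive_days:
        number of consecutive successful sessions required to advance.
    max_sessions:
        hard cap on sessions at this stage.  Reaching it without meeting the
        criterion leads to exclusion, unless ``last_session_min_trials`` is
        set, in which case an animal that still attempts at least that many
        trials on the final session is moved on (forced advancement).
    fixed_sessions:
        probe stages: run exactly this many sessions, then advance; no
        exclusion.
    """

    criterion: str = "none"
    required_rewards: int | None = None
    consecutive_days: int = 1
    max_sessions: int | None = None
    last_session_min_trials: int | None = None
    fixed_sessions: int | None = None

    def __post_init__(self) -> None:
        if self.criterion not in ("rewards", "consume", "none"):
            raise ConfigError(f"unknown criterion {self.criterion!r}")
        if self.criterion == "rewards" and self.required_rewards is None:
            raise ConfigError("'rewards' criterion needs required_rewards")
        if self.consecutive_days < 1:
            raise ConfigError("consecutive_days must be >= 1")


@dataclass(frozen=True)
class StageConfig:
    """Full contingency description of one training/testing stage.

    ``target_sequence`` is empty for habituation stages, which instead use
    ``scheduled_delivery_s`` (automatic pellet delivery period) and/or
    ``manual_preload`` (pellets placed in the feeder at session start).
    ``any_lever`` marks basic operant training, where every press of either
    lever is rewarded (target length 1, lever irrelevant).
    """

    stage_id: str
    target_sequence: tuple[str, ...]
    windows: tuple[TimeWindow, ...]
    criteria: AdvancementRule
    timeout_s: float = 5.0
    session_cap_min: float = 60.0
    reward_cap: int = 40
    reinforced: bool = True
    any_lever: bool = False
    alternation: Alternation | None = None
    trial_cap: int | None = None
    scheduled_delivery_s: float | None = None
    manual_preload: int = 0

    def __post_init__(self) -> None:
        if any(s not in (LEFT, RIGHT) for s in self.target_sequence):
            raise ConfigError(
                f"stage {self.stage_id}: target_sequence must contain only L/R"
            )
        if self.target_sequence and len(self.windows) != len(self.target_sequence) - 1:
            raise ConfigError(
                f"stage {self.stage_id}: expected {len(self.target_sequence) - 1} "
                f"windows for a {len(self.target_sequence)}-press sequence, "
                f"got {len(self.windows)}"
            )
        if not self.target_sequence and self.windows:
            raise ConfigError(f"stage {self.stage_id}: windows without a sequence")
        if self.reward_cap <= 0 or self.session_cap_min <= 0:
            raise ConfigError(
                f"stage {self.stage_id}: reward_cap and session_cap_min must be positive"
            )
        if self.timeout_s < 0:
            raise ConfigError(f"stage {self.stage_id}: negative timeout")
        if self.any_lever and len(self.target_sequence) != 1:
            raise ConfigError(
                f"stage {self.stage_id}: any_lever requires a length-1 sequence"
            )
        if self.alternation is not None and len(
            self.alternation.alternate_sequence
        ) > len(self.target_sequence):
            raise ConfigError(
                f"stage {self.stage_id}: alternate sequence longer than base"
            )

    @property
    def is_habituation(self) -> bool:
        return not self.target_sequence

    @property
    def session_cap_s(self) -> float:
        return self.session_cap_min * 60.0

    def fingerprint(self) -> str:
        """Short stable digest of the full configuration."""
        doc = yaml.safe_dump(_stage_to_dict(self), sort_keys=True)
        return hashlib.sha1(doc.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Builtin stages: the canonical 15-stage protocol.
# ---------------------------------------------------------------------------

_BASELINE_WINDOWS = (TimeWindow(0.5, 5.0), TimeWindow(0.5, 20.0), TimeWindow(0.5, 5.0))

_RULE_40x3 = AdvancementRule(
    criterion="rewards", required_rewards=40, consecutive_days=3, max_sessions=10
)
_RULE_TIMED = AdvancementRule(
    criterion="rewards",
    required_rewards=40,
    consecutive_days=3,
    max_sessions=10,
    last_session_min_trials=10,
)
_RULE_PROBE = AdvancementRule(criterion="none", fixed_sessions=3)


def _timed_llrr(stage_id: str, windows, **kw) -> StageConfig:
    return StageConfig(
        stage_id=stage_id,
        target_sequence=(LEFT, LEFT, RIGHT, RIGHT),
        windows=tuple(windows),
        criteria=kw.pop("criteria", _RULE_PROBE),
        **kw,
    )


def _builtins() -> dict[str, StageConfig]:
    stages = [
        StageConfig(
            stage_id="habituation1",
            target_sequence=(),
            windows=(),
            session_cap_min=10.0,
            reward_cap=1,  # no delivery ever occurs; cap is unreachable
            timeout_s=0.0,
            criteria=AdvancementRule(criterion="none", fixed_sessions=1),
        ),
        StageConfig(
            stage_id="habituation2",
            target_sequence=(),
            windows=(),
            session_cap_min=10.0,
            reward_cap=4,
            manual_preload=4,
            timeout_s=0.0,
            criteria=AdvancementRule(criterion="consume", max_sessions=10),
        ),
        StageConfig(
            stage_id="habituation3",
            target_sequence=(),
            windows=(),
            session_cap_min=30.0,
            reward_cap=15,
            scheduled_delivery_s=120.0,
            timeout_s=0.0,
            criteria=AdvancementRule(criterion="consume", max_sessions=10),
        ),
        StageConfig(
            stage_id="operant_training",
            target_sequence=(LEFT,),
            windows=(),
            any_lever=True,
            session_cap_min=30.0,
            reward_cap=40,
            timeout_s=0.0,
            criteria=AdvancementRule(
                criterion="rewards",
                required_rewards=40,
                consecutive_days=1,
                max_sessions=10,
            ),
        ),
        StageConfig(
            stage_id="LR",
            target_sequence=(LEFT, RIGHT),
            windows=(UNTIMED,),
            criteria=_RULE_40x3,
        ),
        StageConfig(
            stage_id="LLR",
            target_sequence=(LEFT, LEFT, RIGHT),
            windows=(UNTIMED, UNTIMED),
            criteria=_RULE_40x3,
        ),
        StageConfig(
            stage_id="LLRR",
            target_sequence=(LEFT, LEFT, RIGHT, RIGHT),
            windows=(UNTIMED, UNTIMED, UNTIMED),
            criteria=_RULE_40x3,
        ),
        _timed_llrr("LLRR_baseline", _BASELINE_WINDOWS, criteria=_RULE_TIMED),
        _timed_llrr(
            "LLRR_strict",
            (TimeWindow(0.5, 2.0), TimeWindow(0.5, 10.0), TimeWindow(0.5, 2.0)),
            criteria=_RULE_TIMED,
        ),
        _timed_llrr(
            "LLRR_alternating",
            _BASELINE_WINDOWS,
            alternation=Alternation(period=4, alternate_sequence=(LEFT, LEFT, RIGHT)),
        ),
        _timed_llrr(
            "LLRR_rebaseline",
            _BASELINE_WINDOWS,
            criteria=AdvancementRule(
                criterion="rewards",
                required_rewards=40,
                consecutive_days=1,
                max_sessions=3,
                last_session_min_trials=10,
            ),
        ),
        _timed_llrr(
            "LLRR_left",
            (TimeWindow(1.5, 5.0), TimeWindow(0.5, 20.0), TimeWindow(0.5, 5.0)),
        ),
        _timed_llrr(
            "LLRR_right",
            (TimeWindow(0.5, 5.0), TimeWindow(0.5, 20.0), TimeWindow(1.5, 5.0)),
        ),
        _timed_llrr(
            "LLRR_middle",
            (TimeWindow(0.5, 5.0), TimeWindow(3.0, 20.0), TimeWindow(0.5, 5.0)),
        ),
        _timed_llrr(
            "Extinction",
            _BASELINE_WINDOWS,
            reinforced=False,
            trial_cap=40,
            criteria=AdvancementRule(criterion="none", fixed_sessions=1),
        ),
    ]
    return {s.stage_id: s for s in stages}


_BUILTINS = _builtins()

#: Canonical stage order of the full protocol (the re-establishment
#: baseline recurs between probes in the live study; here it appears once
#: as a distinct stage id).
STAGE_ORDER: tuple[str, ...] = tuple(_BUILTINS)


def builtin_stage(stage_id: str) -> StageConfig:
    """Return the canonical configuration of a builtin stage.

    Raises ``ConfigError`` listing the valid names for an unknown id.
    """
    try:
        return _BUILTINS[stage_id]
    except KeyError:
        raise ConfigError(
            f"unknown stage {stage_id!r}; valid stages: {', '.join(STAGE_ORDER)}"
        ) from None


def canonical_protocol() -> list[StageConfig]:
    """The full 15-stage protocol in canonical order."""
    return [builtin_stage(s) for s in STAGE_ORDER]


# ---------------------------------------------------------------------------
# Protocol documents (YAML, one stage per block).
# ---------------------------------------------------------------------------

_STAGE_FIELDS = {f.name for f in dataclasses.fields(StageConfig)}


def _stage_to_dict(cfg: StageConfig) -> dict[str, Any]:
    d: dict[str, Any] = {
        "stage": cfg.stage_id,
        "target_sequence": "".join(cfg.target_sequence),
        "windows": [w.as_pair() for w in cfg.windows],
        "timeout_s": cfg.timeout_s,
        "session_cap_min": cfg.session_cap_min,
        "reward_cap": cfg.reward_cap,
        "reinforced": cfg.reinforced,
        "any_lever": cfg.any_lever,
        "manual_preload": cfg.manual_preload,
    }
    if cfg.trial_cap is not None:
        d["trial_cap"] = cfg.trial_cap
    if cfg.scheduled_delivery_s is not None:
        d["scheduled_delivery_s"] = cfg.scheduled_delivery_s
    if cfg.alternation is not None:
        d["alternation"] = {
            "period": cfg.alternation.period,
            "alternate_sequence": "".join(cfg.alternation.alternate_sequence),
        }
    r = cfg.criteria
    crit: dict[str, Any] = {"criterion": r.criterion}
    if r.required_rewards is not None:
        crit["required_rewards"] = r.required_rewards
    if r.consecutive_days != 1:
        crit["consecutive_days"] = r.consecutive_days
    if r.max_sessions is not None:
        crit["max_sessions"] = r.max_sessions
    if r.last_session_min_trials is not None:
        crit["last_session_min_trials"] = r.last_session_min_trials
    if r.fixed_sessions is not None:
        crit["fixed_sessions"] = r.fixed_sessions
    d["criteria"] = crit
    return d


def _stage_from_dict(block: dict[str, Any]) -> StageConfig:
    if not isinstance(block, dict) or "stage" not in block:
        raise ProtocolError(f"stage block missing 'stage' key: {block!r}")
    stage_id = str(block["stage"])
    base = _BUILTINS.get(stage_id)
    # Start from builtin defaults when the id is known, so documents only
    # need to state overrides.
    d = _stage_to_dict(base) if base is not None else {}
    d.update(block)

    def fail(field_name: str, msg: str) -> ProtocolError:
        return ProtocolError(f"stage {stage_id!r}, field {field_name!r}: {msg}")

    try:
        seq = tuple(str(d.get("target_sequence", "")))
        windows = tuple(TimeWindow(float(lo), float(hi)) for lo, hi in d.get("windows", []))
    except (TypeError, ValueError) as e:
        raise fail("windows", str(e)) from e
    alt = None
    if d.get("alternation"):
        a = d["alternation"]
        try:
            alt = Alternation(int(a["period"]), tuple(str(a["alternate_sequence"])))
        except (KeyError, TypeError, ValueError, ConfigError) as e:
            raise fail("alternation", str(e)) from e
    crit_d = dict(d.get("criteria") or {"criterion": "none"})
    try:
        rule = AdvancementRule(
            criterion=crit_d.get("criterion", "none"),
            required_rewards=crit_d.get("required_rewards"),
            consecutive_days=int(crit_d.get("consecutive_days", 1)),
            max_sessions=crit_d.get("max_sessions"),
            last_session_min_trials=crit_d.get("last_session_min_trials"),
            fixed_sessions=crit_d.get("fixed_sessions"),
        )
    except ConfigError as e:
        raise fail("criteria", str(e)) from e
    unknown = set(d) - (_STAGE_FIELDS | {"stage", "windows", "alternation", "criteria",
                                         "target_sequence"})
    if unknown:
        raise fail(sorted(unknown)[0], "unknown field")
    try:
        return StageConfig(
            stage_id=stage_id,
            target_sequence=seq,
            windows=windows,
            criteria=rule,
            timeout_s=float(d.get("timeout_s", 5.0)),
            session_cap_min=float(d.get("session_cap_min", 60.0)),
            reward_cap=int(d.get("reward_cap", 40)),
            reinforced=bool(d.get("reinforced", True)),
            any_lever=bool(d.get("any_lever", False)),
            alternation=alt,
            trial_cap=d.get("trial_cap"),
            scheduled_delivery_s=d.get("scheduled_delivery_s"),
            manual_preload=int(d.get("manual_preload", 0)),
        )
    except ConfigError as e:
        raise ProtocolError(f"stage {stage_id!r}: {e}") from e


def load_protocol(source: str | Path | io.TextIOBase) -> list[StageConfig]:
    """Parse an ordered protocol document into stage configurations.

    ``source`` may be a YAML string, a path, or an open text stream.  Stage
    blocks with a known builtin id inherit its defaults; other fields are
    validated per the StageConfig invariants.  Errors name the offending
    stage and field.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and source.endswith((".yaml", ".yml"))
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise ProtocolError(f"protocol document does not parse: {e}") from e
    if isinstance(doc, dict) and "protocol" in doc:
        doc = doc["protocol"]
    if not isinstance(doc, list):
        raise ProtocolError("protocol document must be a list of stage blocks")
    return [_stage_from_dict(b) for b in doc]


def save_protocol(stages: Iterable[StageConfig], sink: str | Path | io.TextIOBase | None = None) -> str:
    """Serialize stages to the protocol document format (round-trips)."""
    doc = yaml.safe_dump(
        {"protocol": [_stage_to_dict(s) for s in stages]},
        sort_keys=False,
        default_flow_style=None,
    )
    if sink is not None:
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(doc)
        else:
            sink.write(doc)
    return doc


def bundled_protocol_path() -> Path:
    """Path to the bundled canonical 15-stage protocol document."""
    return Path(__file__).parent / "data" / "protocol.yaml"
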