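"""Session event streams and the decimal-encoded log dialect.

A session log is a single row of whitespace-separated decimal tokens, one
token per event: the integer part counts 0.01 s clock ticks elapsed since
the previous recorded event, and the fractional part is a fixed-width
three-digit event code (``123.012`` = 1.23 s after the previous event,
code 12).  Header lines prefixed with ``#`` precede each row and carry
animal id, stage, date, and a configuration fingerprint.  This mirrors the
one-row-per-session decimal log convention of operant acquisition software
while fixing a fully documented code table of our own (press roles per
lever, reward, time-out onset/offset, cue lights, session markers).

Per-session summary files are flat ``key: value`` text with a fixed key
order.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

__all__ = [
    "TICK_S",
    "CODES",
    "Codes",
    "Event",
    "SessionLog",
    "SessionSummary",
    "IntervalStats",
    "LogFormatError",
    "write_log",
    "read_log",
    "write_summary",
    "read_summary",
    "press_code",
    "decode_press",
]

#: Clock resolution: all event times are quantized to 0.01 s ticks.
TICK_S = 0.01


def to_ticks(t_s: float) -> int:
    return int(round(t_s / TICK_S))


class Codes:
    """The registered event-code table (closed and versioned)."""

    VERSION = 1

    SESSION_START = 1
    SESSION_END = 2
    # Press codes: tens digit = role, units digit = lever (1=L, 2=R).
    PRESS_CORRECT_L, PRESS_CORRECT_R = 11, 12
    PRESS_INCORRECT_L, PRESS_INCORRECT_R = 21, 22
    PRESS_TOO_FAST_L, PRESS_TOO_FAST_R = 31, 32
    PRESS_TOO_SLOW_L, PRESS_TOO_SLOW_R = 41, 42
    PRESS_TIMEOUT_L, PRESS_TIMEOUT_R = 51, 52
    REWARD = 61
    PELLET_PRELOAD = 62
    TRIAL_COMPLETE = 63
    TIMEOUT_ONSET = 71
    TIMEOUT_OFFSET = 72
    CUE_ON_L, CUE_OFF_L = 81, 82
    CUE_ON_R, CUE_OFF_R = 83, 84


CODES: dict[int, str] = {
    Codes.SESSION_START: "session_start",
    Codes.SESSION_END: "session_end",
    Codes.PRESS_CORRECT_L: "press_correct_L",
    Codes.PRESS_CORRECT_R: "press_correct_R",
    Codes.PRESS_INCORRECT_L: "press_incorrect_L",
    Codes.PRESS_INCORRECT_R: "press_incorrect_R",
    Codes.PRESS_TOO_FAST_L: "press_too_fast_L",
    Codes.PRESS_TOO_FAST_R: "press_too_fast_R",
    Codes.PRESS_TOO_SLOW_L: "press_too_slow_L",
    Codes.PRESS_TOO_SLOW_R: "press_too_slow_R",
    Codes.PRESS_TIMEOUT_L: "press_timeout_L",
    Codes.PRESS_TIMEOUT_R: "press_timeout_R",
    Codes.REWARD: "reward",
    Codes.PELLET_PRELOAD: "pellet_preload",
    Codes.TRIAL_COMPLETE: "trial_complete",
    Codes.TIMEOUT_ONSET: "timeout_onset",
    Codes.TIMEOUT_OFFSET: "timeout_offset",
    Codes.CUE_ON_L: "cue_on_L",
    Codes.CUE_OFF_L: "cue_off_L",
    Codes.CUE_ON_R: "cue_on_R",
    Codes.CUE_OFF_R: "cue_off_R",
}

_ROLE_TENS = {"correct": 1, "incorrect": 2, "too_fast": 3, "too_slow": 4, "timeout": 5}
_TENS_ROLE = {v: k for k, v in _ROLE_TENS.items()}
PRESS_ROLES = tuple(_ROLE_TENS)


def press_code(role: str, lever: str) -> int:
    """Event code for a press of ``lever`` ('L'/'R') with the given role."""
    return _ROLE_TENS[role] * 10 + (1 if lever == "L" else 2)


def decode_press(code: int) -> tuple[str, str] | None:
    """(role, lever) for a press code, or None for non-press codes."""
    tens, units = divmod(code, 10)
    if tens in _TENS_ROLE and units in (1, 2):
        return _TENS_ROLE[tens], "L" if units == 1 else "R"
    return None


class LogFormatError(ValueError):
    """A log document violates the dialect (reported with row/column)."""


@dataclass(frozen=True)
class Event:
    """One time-stamped coded occurrence in a session stream."""

    ticks: int  # absolute time in 0.01 s ticks from session start
    code: int

    @property
    def t(self) -> float:
        """Absolute time in seconds from session start."""
        return self.ticks * TICK_S

    @property
    def name(self) -> str:
        return CODES.get(self.code, f"unknown_{self.code}")


@dataclass
class IntervalStats:
    """Summary of one transition's realized interpress intervals."""

    n: int
    mean: float
    sd: float
    cv: float


@dataclass
class SessionSummary:
    """Per-session derived parameters.

    The engine fills the count fields from its internal tallies; the
    analysis module recomputes everything (including categories, interval
    statistics, bouts/pauses and cumulative curves) from the event stream
    alone — equality of the two routes is the core integrity check.
    """

    stage_id: str = ""
    duration_s: float = 0.0
    rewards: int = 0
    completed_trials: int = 0
    trials_attempted: int = 0
    press_counts: dict[str, dict[str, int]] = field(
        default_factory=lambda: {r: {"L": 0, "R": 0} for r in PRESS_ROLES}
    )
    category_counts: dict[str, int] = field(default_factory=dict)
    interval_stats: dict[str, IntervalStats] = field(default_factory=dict)
    bout_durations: list[float] = field(default_factory=list)
    pause_durations: list[float] = field(default_factory=list)
    cumulative: dict[str, list[tuple[float, int]]] = field(default_factory=dict)

    # -- press accounting -------------------------------------------------
    def role_count(self, role: str, lever: str | None = None) -> int:
        by_lever = self.press_counts.get(role, {})
        if lever is not None:
            return by_lever.get(lever, 0)
        return sum(by_lever.values())

    @property
    def total_presses(self) -> int:
        return sum(self.role_count(r) for r in PRESS_ROLES)

    @property
    def correct_presses(self) -> int:
        return self.role_count("correct")

    @property
    def incorrect_presses(self) -> int:
        """Error presses: wrong lever plus timing errors (not TO presses)."""
        return sum(self.role_count(r) for r in ("incorrect", "too_fast", "too_slow"))

    @property
    def timeout_presses(self) -> int:
        return self.role_count("timeout")

    def lever_count(self, lever: str) -> int:
        return sum(self.role_count(r, lever) for r in PRESS_ROLES)

    def to_flat(self) -> dict[str, Any]:
        """Ordered flat mapping used by the summary file format."""
        d: dict[str, Any] = {
            "stage": self.stage_id,
            "duration_s": round(self.duration_s, 2),
            "rewards": self.rewards,
            "completed_trials": self.completed_trials,
            "trials_attempted": self.trials_attempted,
            "total_presses": self.total_presses,
            "correct_presses": self.correct_presses,
            "incorrect_presses": self.incorrect_presses,
            "timeout_presses": self.timeout_presses,
            "left_presses": self.lever_count("L"),
            "right_presses": self.lever_count("R"),
        }
        for role in PRESS_ROLES:
            for lever in ("L", "R"):
                d[f"presses_{role}_{lever}"] = self.role_count(role, lever)
        for label in sorted(self.category_counts):
            d[f"category.{label}"] = self.category_counts[label]
        for name in sorted(self.interval_stats):
            s = self.interval_stats[name]
            d[f"interval.{name}.n"] = s.n
            d[f"interval.{name}.mean"] = round(s.mean, 4)
            d[f"interval.{name}.sd"] = round(s.sd, 4)
            d[f"interval.{name}.cv"] = round(s.cv, 4)
        return d


@dataclass
class SessionLog:
    """One session: header, time-ordered events, optional summary."""

    header: dict[str, str] = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)
    summary: SessionSummary | None = None
    unknown_codes: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        last = 0
        for ev in self.events:
            if ev.ticks < last:
                raise LogFormatError("events are not time-ordered")
            last = ev.ticks

    @property
    def stage_id(self) -> str:
        return self.header.get("stage", "")

    def presses(self) -> list[tuple[float, str, str]]:
        """(time_s, lever, role) for every press event, in order."""
        out = []
        for ev in self.events:
            rl = decode_press(ev.code)
            if rl is not None:
                out.append((ev.t, rl[1], rl[0]))
        return out


# ---------------------------------------------------------------------------
# Log document I/O
# ---------------------------------------------------------------------------

_HEADER_ORDER = ("animal", "stage", "session", "date", "config")


def _format_row(events: Iterable[Event]) -> str:
    tokens = []
    prev = 0
    for ev in events:
        if ev.code not in CODES:
            raise LogFormatError(f"unregistered event code {ev.code}")
        tokens.append(f"{ev.ticks - prev}.{ev.code:03d}")
        prev = ev.ticks
    return " ".join(tokens)


def write_log(
    logs: SessionLog | Iterable[SessionLog],
    sink: str | Path | io.TextIOBase | None = None,
) -> str:
    """Serialize session logs: header lines then one event row per session.

    The output is bit-stable: identical logs serialize to identical text.
    """
    if isinstance(logs, SessionLog):
        logs = [logs]
    lines: list[str] = []
    for log in logs:
        for key in _HEADER_ORDER:
            if key in log.header:
                lines.append(f"# {key}: {log.header[key]}")
        for key in sorted(set(log.header) - set(_HEADER_ORDER)):
            lines.append(f"# {key}: {log.header[key]}")
        lines.append(_format_row(log.events))
    doc = "\n".join(lines) + "\n"
    if sink is not None:
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(doc)
        else:
            sink.write(doc)
    return doc


def _parse_row(line: str, row_no: int, warn_codes: set[int]) -> list[Event]:
    events: list[Event] = []
    ticks = 0
    col = 1
    for token in line.split():
        jcol = line.index(token, col - 1) + 1
        parts = token.split(".")
        if len(parts) != 2 or not parts[0].isdigit() or not parts[1].isdigit():
            raise LogFormatError(
                f"row {row_no}, column {jcol}: malformed token {token!r} "
                "(expected <ticks>.<3-digit code>)"
            )
        dt, code = int(parts[0]), int(parts[1])
        ticks += dt
        if code not in CODES:
            warn_codes.add(code)
        events.append(Event(ticks=ticks, code=code))
        col = jcol + len(token)
    return events


def read_log(source: str | Path | io.TextIOBase) -> list[SessionLog]:
    """Parse a log document into session logs.

    Absolute event times are prefix sums of the per-token tick deltas.
    Unknown codes are retained and collected into ``SessionLog.unknown_codes``
    (with a warning) rather than dropped.  Malformed tokens raise
    ``LogFormatError`` with row and column.
    """
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)

    logs: list[SessionLog] = []
    header: dict[str, str] | None = None
    for i, line in enumerate(text.split("\n"), start=1):
        stripped = line.strip()
        if stripped.startswith("#"):
            if header is None:
                header = {}
            key, _, value = stripped[1:].partition(":")
            header[key.strip()] = value.strip()
        elif header is not None:
            # First line (possibly empty) after a header block is the row.
            warn_codes: set[int] = set()
            events = _parse_row(line, i, warn_codes)
            if warn_codes:
                warnings.warn(
                    f"row {i}: unregistered event codes {sorted(warn_codes)}",
                    stacklevel=2,
                )
            logs.append(
                SessionLog(
                    header=header, events=events, unknown_codes=sorted(warn_codes)
                )
            )
            header = None
        elif stripped:
            raise LogFormatError(f"row {i}: event row without a header block")
    if header is not None:
        # Header at end of document with no row line at all.
        logs.append(SessionLog(header=header, events=[]))
    return logs


# ---------------------------------------------------------------------------
# Summary files
# ---------------------------------------------------------------------------


def write_summary(
    summary: SessionSummary, sink: str | Path | io.TextIOBase | None = None
) -> str:
    """Render a summary as flat ``key: value`` text with fixed key order."""
    flat = summary.to_flat() if hasattr(summary, "to_flat") else dict(summary)
    doc = "".join(f"{k}: {v}\n" for k, v in flat.items())
    if sink is not None:
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(doc)
        else:
            sink.write(doc)
    return doc


def read_summary(source: str | Path | io.TextIOBase) -> dict[str, str]:
    """Parse a summary file back into a flat string mapping."""
    if isinstance(source, io.TextIOBase):
        text = source.read()
    elif isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    out: dict[str, str] = {}
    for line in text.splitlines():
        if not line.strip():
            continue
        key, _, value = line.partition(":")
        out[key.strip()] = value.strip()
    return out
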