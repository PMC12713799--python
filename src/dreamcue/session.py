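"""Timer-driven targeted dream incubation (TDI) sessions.

A session alternates incubation cues ("Remember to think of a Fork/Tree"),
dwell periods in the target state (hypnagogia or freely moving thought),
report prompts, and return-to-state periods.  Because the protocol is
sensor-free, every event is scheduled purely from timing parameters: a
participant-chosen sleep-latency window followed by a fixed per-trial
structure.  The module builds those schedules deterministically, executes
them against an injectable clock, and applies the vigilance-based screen
used to decide whether a participant's pair of sessions is analyzable.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from datetime import datetime, timezone
from enum import Enum
from typing import Callable, Iterable, Optional

import numpy as np

__all__ = [
    "Condition",
    "CueObject",
    "VigilanceLevel",
    "SessionConfig",
    "CueScript",
    "TimelineEvent",
    "SessionTimeline",
    "VigilanceResponse",
    "EventRecord",
    "EventLog",
    "SimulatedClock",
    "WallClock",
    "draw_latency",
    "build_timeline",
    "run_session",
    "inclusion_filter",
    "screen_cohort",
]


class Condition(str, Enum):
    HYPNAGOGIA = "hypnagogia"
    FMT = "fmt"


class CueObject(str, Enum):
    FORK = "Fork"
    TREE = "Tree"


class VigilanceLevel(str, Enum):
    FULLY_ASLEEP = "fully_asleep"
    HALF_ASLEEP = "half_asleep"
    DID_NOT_SLEEP = "did_not_sleep"


class EventKind(str, Enum):
    SESSION_START = "session_start"
    INCUBATION_CUE = "incubation_cue"
    DWELL_START = "dwell_start"
    REPORT_PROMPT = "report_prompt"
    REPORT_END = "report_end"
    RETURN_START = "return_start"
    SESSION_END = "session_end"


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one TDI session.

    Defaults mirror the standard protocol: 3-minute dwells, 4 trials,
    60-second report windows and 7-minute return periods, with the
    latency window freely chosen by the participant.
    """

    participant_id: str
    condition: Condition
    cue_object: CueObject
    latency_min_s: int
    latency_max_s: int
    dwell_s: int = 180
    n_trials: int = 4
    report_s: int = 60
    return_s: int = 420
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.latency_min_s <= self.latency_max_s):
            raise ValueError(
                f"latency window invalid: [{self.latency_min_s}, {self.latency_max_s}]"
            )
        for name in ("dwell_s", "report_s", "return_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        object.__setattr__(self, "condition", Condition(self.condition))
        object.__setattr__(self, "cue_object", CueObject(self.cue_object))


@dataclass(frozen=True)
class CueScript:
    """The two self-recorded prompt messages of a session."""

    cue_object: CueObject
    incubation_text: str = ""
    report_text: str = "Tell me what is going through your mind"

    def __post_init__(self) -> None:
        if not self.incubation_text:
            object.__setattr__(
                self,
                "incubation_text",
                f"Remember to think of a {CueObject(self.cue_object).value}",
            )
        if not self.report_text:
            raise ValueError("report_text must be non-empty")
        word = CueObject(self.cue_object).value.lower()
        n = self.incubation_text.lower().split().count(word)
        if n != 1:
            raise ValueError(
                f"incubation_text must mention {word!r} exactly once (found {n})"
            )


@dataclass(frozen=True)
class TimelineEvent:
    offset_s: int
    kind: EventKind
    trial_index: Optional[int] = None  # 1-based; None for session-level events


@dataclass(frozen=True)
class SessionTimeline:
    config: SessionConfig
    latency_s: int
    events: tuple[TimelineEvent, ...]

    @property
    def total_duration_s(self) -> int:
        return self.events[-1].offset_s

    def count(self, kind: EventKind) -> int:
        return sum(1 for e in self.events if e.kind == kind)


@dataclass(frozen=True)
class VigilanceResponse:
    condition: Condition
    level: VigilanceLevel

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        object.__setattr__(self, "level", VigilanceLevel(self.level))


def draw_latency(config: SessionConfig, rng: np.random.Generator | None = None) -> int:
    """Draw the pre-cue latency: a uniform integer number of seconds in the
    participant's chosen window (both endpoints included).

    ``rng`` defaults to a fresh generator seeded with ``config.rng_seed`` so
    repeated sessions with the same config reproduce the same draw.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    return int(rng.integers(config.latency_min_s, config.latency_max_s + 1))


def build_timeline(config: SessionConfig, latency_s: int) -> SessionTimeline:
    """Lay out every scheduled event of a session at integer second offsets.

    Structure: session_start at 0; after the latency, each of the
    ``n_trials`` trials is a cue + dwell followed by a report window; the
    trials are separated by return periods (cue replayed at the start of
    each return so that every dwell is preceded by a cue).  The session
    ends with the last report window.
    """
    if not (config.latency_min_s <= latency_s <= config.latency_max_s):
        raise ValueError(
            f"latency {latency_s}s outside configured window "
            f"[{config.latency_min_s}, {config.latency_max_s}]"
        )
    ev: list[TimelineEvent] = [TimelineEvent(0, EventKind.SESSION_START)]
    t = latency_s
    for trial in range(1, config.n_trials + 1):
        ev.append(TimelineEvent(t, EventKind.INCUBATION_CUE, trial))
        ev.append(TimelineEvent(t, EventKind.DWELL_START, trial))
        t += config.dwell_s
        ev.append(TimelineEvent(t, EventKind.REPORT_PROMPT, trial))
        t += config.report_s
        ev.append(TimelineEvent(t, EventKind.REPORT_END, trial))
        if trial < config.n_trials:
            ev.append(TimelineEvent(t, EventKind.RETURN_START, trial))
            t += config.return_s
    ev.append(TimelineEvent(t, EventKind.SESSION_END))
    return SessionTimeline(config=config, latency_s=latency_s, events=tuple(ev))


# ---------------------------------------------------------------------------
# Execution


class SimulatedClock:
    """A clock that jumps instantly (or at ``1/speedup`` real pace) to each
    requested offset.  ``speedup=None`` means fully virtual time."""

    def __init__(self, speedup: float | None = None, start: float = 0.0):
        self.speedup = speedup
        self._now = float(start)

    def now(self) -> float:
        return self._now

    def sleep_until(self, t: float) -> None:
        if t < self._now:
            raise RuntimeError(f"clock asked to move backwards: {t} < {self._now}")
        if self.speedup:
            _time.sleep((t - self._now) / self.speedup)
        self._now = t


class WallClock:
    """Real time, for actually running a session."""

    def __init__(self) -> None:
        self._t0 = _time.monotonic()

    def now(self) -> float:
        return _time.monotonic() - self._t0

    def sleep_until(self, t: float) -> None:
        now = self.now()
        if t < now - 1e-6:
            raise RuntimeError(f"clock asked to move backwards: {t} < {now}")
        if t > now:
            _time.sleep(t - now)


@dataclass(frozen=True)
class EventRecord:
    timestamp: str  # ISO-8601, when the event was realized
    offset_s: int  # scheduled offset
    realized_s: float  # clock reading when emitted
    kind: EventKind
    trial_index: Optional[int]

    def to_line(self) -> str:
        trial = "" if self.trial_index is None else str(self.trial_index)
        return f"{self.timestamp}\t{self.offset_s}\t{self.realized_s:.3f}\t{self.kind.value}\t{trial}"


@dataclass
class EventLog:
    records: list[EventRecord] = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("timestamp\toffset_s\trealized_s\tevent_kind\ttrial_index\n")
            for r in self.records:
                fh.write(r.to_line() + "\n")


def run_session(
    timeline: SessionTimeline,
    clock=None,
    event_sink: Callable[[EventRecord], None] | None = None,
) -> EventLog:
    """Execute a timeline against a clock, emitting each event exactly once,
    in order.  With a :class:`SimulatedClock` the realized offsets equal the
    scheduled offsets exactly; on a wall clock sub-second jitter is recorded
    but never alters the schedule.
    """
    if not timeline.events:
        raise ValueError("cannot run an empty timeline")
    if clock is None:
        clock = SimulatedClock()
    log = EventLog()
    for event in timeline.events:
        clock.sleep_until(event.offset_s)
        rec = EventRecord(
            timestamp=datetime.now(timezone.utc).isoformat(),
            offset_s=event.offset_s,
            realized_s=clock.now(),
            kind=event.kind,
            trial_index=event.trial_index,
        )
        log.records.append(rec)
        if event_sink is not None:
            event_sink(rec)
    return log


# ---------------------------------------------------------------------------
# Inclusion screen


def inclusion_filter(hyp: VigilanceResponse, fmt: VigilanceResponse) -> bool:
    """Vigilance-based analysis inclusion: keep a participant only if they
    stayed completely awake during FMT and slept at least halfway during
    the hypnagogia session."""
    if hyp is None or fmt is None:
        raise ValueError("one vigilance response per condition is required")
    if hyp.condition != Condition.HYPNAGOGIA or fmt.condition != Condition.FMT:
        raise ValueError("responses must be (hypnagogia, fmt) in that order")
    return fmt.level == VigilanceLevel.DID_NOT_SLEEP and hyp.level in (
        VigilanceLevel.FULLY_ASLEEP,
        VigilanceLevel.HALF_ASLEEP,
    )


def screen_cohort(vigilance: "pd.DataFrame") -> "pd.DataFrame":
    """Apply :func:`inclusion_filter` to a long table with columns
    ``participant_id, condition, level`` (one row per participant x
    condition).  Returns a table ``participant_id, included``."""
    import pandas as pd

    out = []
    for pid, grp in vigilance.groupby("participant_id", sort=True):
        by_cond = {Condition(c): VigilanceLevel(l) for c, l in zip(grp["condition"], grp["level"])}
        if set(by_cond) != {Condition.HYPNAGOGIA, Condition.FMT}:
            raise ValueError(f"participant {pid}: need exactly one response per condition")
        ok = inclusion_filter(
            VigilanceResponse(Condition.HYPNAGOGIA, by_cond[Condition.HYPNAGOGIA]),
            VigilanceResponse(Condition.FMT, by_cond[Condition.FMT]),
        )
        out.append({"participant_id": pid, "included": ok})
    return pd.DataFrame(out)
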