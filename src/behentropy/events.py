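"""In-memory event-log containers and invariant checking.

A :class:`Session` is one continuous observation window (in the study design
this emulates, a 50-minute watch). Time is measured in whole seconds from the
window start; scored intervals are half-open ``[start, end)`` so adjacent
intervals never double-count a second. Gaps between intervals are unscored
time, not a behavior state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import EventValidationError
from .ethogram import Ethogram

GROUPS = ("CTL", "LBN")
PHASES = ("light", "dark")


@dataclass(frozen=True)
class Interval:
    start: int
    end: int
    behavior: str

    @property
    def duration(self) -> int:
        return self.end - self.start


@dataclass
class Session:
    """One observation window of a single dam."""

    session_id: str
    phase: str
    day: int
    window_start: int
    window_end: int
    intervals: list[Interval] = field(default_factory=list)

    @property
    def scored_time(self) -> int:
        return sum(iv.duration for iv in self.intervals)


@dataclass
class EventLog:
    """All observation sessions of one dam, with study metadata."""

    dam_id: str
    group: str
    cohort: str
    sessions: list[Session] = field(default_factory=list)

    def phases(self) -> tuple[str, ...]:
        return tuple(p for p in PHASES if any(s.phase == p for s in self.sessions))

    def sessions_in_phase(self, phase: str | None) -> list[Session]:
        """Sessions in scope: ``phase`` of ``light``/``dark``, or None for all."""
        if phase is None or phase == "pooled":
            return list(self.sessions)
        return [s for s in self.sessions if s.phase == phase]


@dataclass
class ValidationReport:
    """Outcome of checking an event log against the session invariants.

    ``errors`` and ``warnings`` are lists of ``(session_id, rule, detail)``.
    """

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def is_valid(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = []
        for sid, rule, detail in self.errors:
            lines.append(f"ERROR   [{rule}] session {sid}: {detail}")
        for sid, rule, detail in self.warnings:
            lines.append(f"WARNING [{rule}] session {sid}: {detail}")
        return "\n".join(lines) or "valid"


def validate_event_log(log: EventLog, ethogram: Ethogram) -> ValidationReport:
    """Check every session invariant; violations are reported, not raised.

    Rules checked per session: metadata values, interval ordering, positive
    duration, window bounds, non-overlap (a dam performs one scored behavior
    at a time), and ethogram membership of every label.
    """
    report = ValidationReport()
    err = report.errors.append

    if log.group not in GROUPS:
        err(("-", "group", f"unknown group {log.group!r}"))
    seen_ids = set()
    for sess in log.sessions:
        sid = sess.session_id
        if sid in seen_ids:
            err((sid, "session_id", "duplicate session id"))
        seen_ids.add(sid)
        if sess.phase not in PHASES:
            err((sid, "phase", f"unknown phase {sess.phase!r}"))
        if sess.day < 1:
            err((sid, "day", f"day must be >= 1, got {sess.day}"))
        if sess.window_end <= sess.window_start:
            err((sid, "window", "window_end must exceed window_start"))
        prev_end = None
        prev_start = None
        for i, iv in enumerate(sess.intervals):
            where = f"interval {i} [{iv.start},{iv.end}) {iv.behavior!r}"
            if iv.end <= iv.start:
                err((sid, "duration", f"{where}: end must exceed start"))
            if prev_start is not None and iv.start < prev_start:
                err((sid, "order", f"{where}: intervals not sorted by start"))
            if iv.start < sess.window_start or iv.end > sess.window_end:
                err((sid, "bounds", f"{where}: outside window "
                     f"[{sess.window_start},{sess.window_end})"))
            if prev_end is not None and iv.start < prev_end:
                err((sid, "overlap", f"{where}: overlaps previous interval"))
            if iv.behavior not in ethogram:
                err((sid, "label", f"{where}: behavior not in ethogram"))
            prev_start = iv.start
            prev_end = max(prev_end, iv.end) if prev_end is not None else iv.end
    return report


def require_valid(log: EventLog, ethogram: Ethogram) -> None:
    """Raise :class:`EventValidationError` if the log fails validation."""
    report = validate_event_log(log, ethogram)
    if not report.is_valid:
        raise EventValidationError(
            f"event log for dam {log.dam_id!r} is invalid:\n{report}"
        )
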