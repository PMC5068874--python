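"""Reading and writing the behavior event-log CSV dialect.

The dialect is a plain UTF-8 CSV with the header
``dam_id,group,cohort,phase,day,session_id,start_s,end_s,behavior`` where
``start_s``/``end_s`` are non-negative integer seconds from the start of the
session window and each row is one scored interval. A single file may hold
one dam or a whole study. Round-tripping a valid log through
:func:`write_event_log` and :func:`read_event_log` is exact.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .errors import EventValidationError, FormatError
from .ethogram import Ethogram
from .events import (
    EventLog,
    Interval,
    Session,
    require_valid,
    validate_event_log,
)

COLUMNS = [
    "dam_id", "group", "cohort", "phase", "day",
    "session_id", "start_s", "end_s", "behavior",
]

#: Default session window length: one 50-minute observation period.
DEFAULT_SESSION_LENGTH_S = 3000


def _sessions_from_frame(df: pd.DataFrame, session_length_s: int) -> list[Session]:
    sessions = []
    for sid, rows in df.groupby("session_id", sort=False):
        phases = rows["phase"].unique()
        days = rows["day"].unique()
        if len(phases) > 1 or len(days) > 1:
            raise FormatError(
                f"session {sid!r} has inconsistent phase/day metadata"
            )
        ivs = [
            Interval(int(r.start_s), int(r.end_s), str(r.behavior))
            for r in rows.sort_values("start_s").itertuples()
        ]
        sessions.append(
            Session(
                session_id=str(sid),
                phase=str(phases[0]),
                day=int(days[0]),
                window_start=0,
                window_end=int(session_length_s),
                intervals=ivs,
            )
        )
    return sessions


def read_study(
    path,
    ethogram: Ethogram,
    strict: bool = True,
    session_length_s: int = DEFAULT_SESSION_LENGTH_S,
) -> list[EventLog]:
    """Read an event-log CSV that may contain several dams.

    In non-strict mode rows whose behavior is not in the ethogram are dropped
    with a warning (analyses routinely use behavior subsets); in strict mode
    they are an error. Structural invariant violations (overlaps, reversed
    intervals, out-of-window times) are always errors.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")

    if len(df) == 0:
        warnings.warn(f"{path}: event table is empty", stacklevel=2)
        return []

    for col in ("start_s", "end_s", "day"):
        try:
            df[col] = df[col].astype(int)
        except (TypeError, ValueError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna()].index[0]
            raise FormatError(
                f"{path}: non-integer {col!r} on data row {bad + 1}"
            ) from exc
    if (df["start_s"] < 0).any():
        bad = int(df.index[df["start_s"] < 0][0])
        raise FormatError(f"{path}: negative start_s on data row {bad + 1}")
    reversed_rows = df.index[df["end_s"] <= df["start_s"]]
    if len(reversed_rows):
        bad = int(reversed_rows[0])
        raise EventValidationError(
            f"{path}: end_s <= start_s on data row {bad + 1}"
        )

    unknown = ~df["behavior"].isin(ethogram.labels)
    if unknown.any():
        rows = [int(i) + 1 for i in df.index[unknown]]
        labels = sorted(df.loc[unknown, "behavior"].unique())
        if strict:
            raise FormatError(
                f"{path}: unknown behavior labels {labels} on rows {rows[:5]}"
            )
        warnings.warn(
            f"{path}: dropped {int(unknown.sum())} rows with behaviors "
            f"outside the ethogram: {labels}",
            stacklevel=2,
        )
        df = df[~unknown]

    logs = []
    for (dam_id, group, cohort), rows in df.groupby(
        ["dam_id", "group", "cohort"], sort=False
    ):
        log = EventLog(
            dam_id=str(dam_id),
            group=str(group),
            cohort=str(cohort),
            sessions=_sessions_from_frame(rows, session_length_s),
        )
        report = validate_event_log(log, ethogram)
        if not report.is_valid:
            raise EventValidationError(
                f"{path}: invalid event log for dam {dam_id!r}:\n{report}"
            )
        logs.append(log)
    return logs


def read_event_log(
    path,
    ethogram: Ethogram,
    strict: bool = True,
    session_length_s: int = DEFAULT_SESSION_LENGTH_S,
) -> EventLog:
    """Read a single-dam event log; error if the file holds several dams."""
    logs = read_study(path, ethogram, strict=strict,
                      session_length_s=session_length_s)
    if len(logs) == 0:
        return EventLog(dam_id="", group="CTL", cohort="", sessions=[])
    if len(logs) > 1:
        raise FormatError(
            f"{path}: expected one dam, found {len(logs)}; use read_study()"
        )
    return logs[0]


def _log_to_frame(log: EventLog) -> pd.DataFrame:
    rows = []
    for sess in log.sessions:
        for iv in sess.intervals:
            rows.append(
                (log.dam_id, log.group, log.cohort, sess.phase, sess.day,
                 sess.session_id, iv.start, iv.end, iv.behavior)
            )
    return pd.DataFrame(rows, columns=COLUMNS)


def write_study(logs: list[EventLog], path, ethogram: Ethogram) -> None:
    """Write several dams' logs to one CSV; refuses invalid logs."""
    for log in logs:
        require_valid(log, ethogram)
    frames = [_log_to_frame(log) for log in logs]
    out = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=COLUMNS)
    )
    out.to_csv(path, index=False)


def write_event_log(log: EventLog, path, ethogram: Ethogram) -> None:
    """Write one dam's event log; refuses to write an invalid log."""
    write_study([log], path, ethogram)
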