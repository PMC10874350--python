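"""Reading, validating and writing keystroke event logs and questionnaire files.

All timestamps are naive local clock time in the study's single timezone;
the analysis bins events by local clock time, so no timezone arithmetic is
performed anywhere in the package.  An event belongs to the calendar date and
time-of-day of its *press* timestamp; the release timestamp is carried along
but unused downstream.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import logging
from pathlib import Path
from typing import Iterator, Mapping

import pandas as pd
import yaml

from .uls8 import ULS8Response

logger = logging.getLogger(__name__)

_TIME_FMT = "%Y-%m-%dT%H:%M:%S.%f"

__all__ = [
    "KeystrokeEvent",
    "EventLog",
    "LoadReport",
    "StudyCalendar",
    "EmptyLogError",
    "read_event_log",
    "write_event_log",
    "read_uls8_file",
    "write_uls8_file",
    "study_week_of",
    "read_calendar",
    "write_calendar",
]


class EmptyLogError(ValueError):
    """Raised when a log file yields zero parseable events."""


@dataclasses.dataclass(frozen=True)
class KeystrokeEvent:
    """A single anonymized key press/release pair (no key identity)."""

    participant_id: str
    press_time: dt.datetime
    release_time: dt.datetime

    def __post_init__(self) -> None:
        if self.release_time < self.press_time:
            raise ValueError(
                f"release_time {self.release_time} precedes press_time {self.press_time}"
            )


@dataclasses.dataclass(frozen=True)
class LoadReport:
    """Row accounting for one log read: parsed, skipped-malformed, out-of-range."""

    n_rows: int = 0
    n_skipped: int = 0
    n_out_of_range: int = 0


@dataclasses.dataclass
class StudyCalendar:
    """Study calendar: ``n_weeks`` seven-day weeks starting at ``start_date``.

    Study week ``w`` (1-based) spans dates ``[start_date + 7*(w-1),
    start_date + 7*w)``, half-open.  The first ``n_adjustment_weeks`` weeks
    are an adjustment period for the newly installed keyboard and are
    excluded from analysis.
    """

    start_date: dt.date
    n_weeks: int = 5
    n_adjustment_weeks: int = 1

    def __post_init__(self) -> None:
        if isinstance(self.start_date, str):
            self.start_date = dt.date.fromisoformat(self.start_date)
        if not 0 <= self.n_adjustment_weeks < self.n_weeks:
            raise ValueError("need 0 <= n_adjustment_weeks < n_weeks")

    @property
    def end_date(self) -> dt.date:
        """First date *after* the study (half-open upper bound)."""
        return self.start_date + dt.timedelta(days=7 * self.n_weeks)

    @property
    def analysis_weeks(self) -> range:
        """1-based week indices retained for analysis (adjustment weeks dropped)."""
        return range(self.n_adjustment_weeks + 1, self.n_weeks + 1)

    def week_of(self, date: dt.date) -> int | None:
        """1-based study week containing ``date``, or None if out of range."""
        offset = (date - self.start_date).days
        if offset < 0 or offset >= 7 * self.n_weeks:
            return None
        return offset // 7 + 1

    def all_dates(self) -> list[dt.date]:
        return [self.start_date + dt.timedelta(days=i) for i in range(7 * self.n_weeks)]

    def analysis_dates(self) -> list[dt.date]:
        """Dates in analysis weeks, ascending."""
        skip = 7 * self.n_adjustment_weeks
        return self.all_dates()[skip:]

    def week_dates(self, week: int) -> list[dt.date]:
        if not 1 <= week <= self.n_weeks:
            raise ValueError(f"week {week} outside 1..{self.n_weeks}")
        first = self.start_date + dt.timedelta(days=7 * (week - 1))
        return [first + dt.timedelta(days=i) for i in range(7)]


def study_week_of(date: dt.date, calendar: StudyCalendar) -> int | None:
    """1-based study week of ``date``; None marks out-of-range dates."""
    return calendar.week_of(date)


@dataclasses.dataclass
class EventLog:
    """One participant's keystroke events, sorted ascending by press time.

    Backed by a DataFrame with columns ``press_time`` and ``release_time``
    (datetime64); logs at realistic activity levels run to ~10^5 events per
    participant, so per-event objects are exposed only through :meth:`events`.
    """

    participant_id: str
    frame: pd.DataFrame
    source_path: str = ""
    load_report: LoadReport = dataclasses.field(default_factory=LoadReport)

    def __post_init__(self) -> None:
        f = self.frame
        if list(f.columns) != ["press_time", "release_time"]:
            f = f.loc[:, ["press_time", "release_time"]]
        # millisecond resolution is the package-wide timestamp contract
        f = f.astype({"press_time": "datetime64[ms]", "release_time": "datetime64[ms]"})
        self.frame = f
        if not f["press_time"].is_monotonic_increasing:
            # stable sort: file order is preserved among equal press times
            self.frame = f.sort_values("press_time", kind="stable").reset_index(drop=True)
        else:
            self.frame = f.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    def events(self) -> Iterator[KeystrokeEvent]:
        for press, release in self.frame.itertuples(index=False):
            yield KeystrokeEvent(
                self.participant_id, press.to_pydatetime(), release.to_pydatetime()
            )

    @classmethod
    def from_events(cls, events: list[KeystrokeEvent], source_path: str = "") -> "EventLog":
        if not events:
            raise EmptyLogError("cannot build an EventLog from zero events")
        pids = {e.participant_id for e in events}
        if len(pids) > 1:
            raise ValueError(f"events span multiple participants: {sorted(pids)}")
        frame = pd.DataFrame(
            {
                "press_time": [e.press_time for e in events],
                "release_time": [e.release_time for e in events],
            }
        )
        return cls(events[0].participant_id, frame, source_path)

    def clip_to_calendar(self, calendar: StudyCalendar) -> "EventLog":
        """Drop events whose press date falls outside the study calendar."""
        dates = self.frame["press_time"].dt.date
        keep = (dates >= calendar.start_date) & (dates < calendar.end_date)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info(
                "participant %s: dropped %d events outside the study calendar",
                self.participant_id,
                n_dropped,
            )
        rep = self.load_report
        return EventLog(
            self.participant_id,
            self.frame.loc[keep],
            self.source_path,
            LoadReport(rep.n_rows, rep.n_skipped, rep.n_out_of_range + n_dropped),
        )


def _parse_frame(raw: pd.DataFrame, path: str) -> tuple[EventLog, int]:
    required = {"participant_id", "press_time", "release_time"}
    missing = required - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    press = pd.to_datetime(raw["press_time"], format="ISO8601", errors="coerce")
    release = pd.to_datetime(raw["release_time"], format="ISO8601", errors="coerce")
    pid_ok = raw["participant_id"].notna()
    ok = press.notna() & release.notna() & pid_ok & (release >= press)
    n_skipped = int((~ok).sum())
    if n_skipped:
        logger.warning("%s: skipped %d malformed rows", path, n_skipped)
    if not ok.any():
        raise EmptyLogError(f"{path}: no parseable keystroke rows")
    pids = raw.loc[ok, "participant_id"].astype(str).unique()
    if len(pids) > 1:
        raise ValueError(f"{path}: multiple participant ids {sorted(pids)}")
    frame = pd.DataFrame({"press_time": press[ok], "release_time": release[ok]})
    n_rows = int(ok.sum())
    log = EventLog(str(pids[0]), frame, path, LoadReport(n_rows, n_skipped, 0))
    return log, n_skipped


def read_event_log(
    path: str | Path,
    format: str | None = None,
    calendar: StudyCalendar | None = None,
) -> EventLog:
    """Read one participant's event log from CSV or JSONL.

    Malformed rows (unparseable timestamps, release before press, missing id)
    are skipped and counted in the returned log's ``load_report``.  If a
    calendar is given, events outside its date range are dropped and counted.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in {".jsonl", ".ndjson"} else "csv"
    if format not in {"csv", "jsonl"}:
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'jsonl'")
    if format == "csv":
        raw = pd.read_csv(path, dtype={"participant_id": str})
    else:
        raw = pd.read_json(path, lines=True, convert_dates=False, dtype={"participant_id": str})
    log, _ = _parse_frame(raw, str(path))
    if calendar is not None:
        log = log.clip_to_calendar(calendar)
    return log


def write_event_log(log: EventLog, path: str | Path, format: str | None = None) -> None:
    """Write a log as CSV or JSONL with millisecond ISO-8601 timestamps."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in {".jsonl", ".ndjson"} else "csv"
    out = pd.DataFrame(
        {
            "participant_id": log.participant_id,
            # truncate %f (microseconds) to milliseconds
            "press_time": log.frame["press_time"].dt.strftime(_TIME_FMT).str[:-3],
            "release_time": log.frame["release_time"].dt.strftime(_TIME_FMT).str[:-3],
        }
    )
    if format == "csv":
        out.to_csv(path, index=False)
    elif format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for row in out.itertuples(index=False):
                fh.write(json.dumps(row._asdict()) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_uls8_file(path: str | Path) -> dict[str, ULS8Response]:
    """Read a questionnaire CSV (participant_id, q1..q8, items in 1..4)."""
    raw = pd.read_csv(path, dtype={"participant_id": str})
    cols = [f"q{i}" for i in range(1, 9)]
    missing = {"participant_id", *cols} - set(raw.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    responses: dict[str, ULS8Response] = {}
    for idx, row in raw.iterrows():
        pid = str(row["participant_id"])
        if pid in responses:
            raise ValueError(f"{path}: duplicate participant id {pid!r}")
        try:
            items = tuple(int(row[c]) for c in cols)
            responses[pid] = ULS8Response(items)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {idx} (participant {pid}): {exc}") from exc
    return responses


def write_uls8_file(responses: Mapping[str, ULS8Response], path: str | Path) -> None:
    rows = [
        {"participant_id": pid, **{f"q{i+1}": v for i, v in enumerate(r.items)}}
        for pid, r in responses.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_calendar(path: str | Path) -> StudyCalendar:
    """Read a calendar config (YAML key-value: start_date, n_weeks, n_adjustment_weeks)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return StudyCalendar(
        start_date=raw["start_date"]
        if isinstance(raw["start_date"], dt.date)
        else dt.date.fromisoformat(str(raw["start_date"])),
        n_weeks=int(raw.get("n_weeks", 5)),
        n_adjustment_weeks=int(raw.get("n_adjustment_weeks", 1)),
    )


def write_calendar(calendar: StudyCalendar, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(
            {
                "start_date": calendar.start_date.isoformat(),
                "n_weeks": calendar.n_weeks,
                "n_adjustment_weeks": calendar.n_adjustment_weeks,
            },
            fh,
        )
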