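"""Diurnal five-bin typing features.

Each day is tiled by five half-open clock-time bins — sleep [00:00, 06:00),
morning [06:00, 12:00), afternoon [12:00, 17:00), evening [17:00, 21:00),
night [21:00, 24:00) — and each keystroke is counted once in the bin of its
press time. Per-day bin counts feed a completeness filter (a study week is
complete when all 7 of its days have at least one keystroke; a participant is
included with at least 3 complete weeks out of the 4 post-adjustment weeks)
and, for included participants, averaged count and count-ratio profiles,
overall and split by weekday/weekend.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .io import EventLog, StudyCalendar

__all__ = [
    "TimeBin",
    "BINS",
    "BIN_LABELS",
    "BIN_EDGES_MINUTES",
    "DailyBinCounts",
    "InclusionDecision",
    "ParticipantProfile",
    "UndefinedProfileError",
    "bin_of",
    "bin_index_of_minutes",
    "daily_bin_counts",
    "day_records",
    "complete_week_set",
    "completeness_filter",
    "participant_profile",
    "profiles_frame",
]


@dataclasses.dataclass(frozen=True)
class TimeBin:
    """A half-open clock-time window [start, end) in minutes after midnight."""

    label: str
    start_minute: int
    end_minute: int


BINS: tuple[TimeBin, ...] = (
    TimeBin("sleep", 0, 360),
    TimeBin("morning", 360, 720),
    TimeBin("afternoon", 720, 1020),
    TimeBin("evening", 1020, 1260),
    TimeBin("night", 1260, 1440),
)

BIN_LABELS: tuple[str, ...] = tuple(b.label for b in BINS)

#: bin edges in minutes after midnight; bin i is [edges[i], edges[i+1])
BIN_EDGES_MINUTES: np.ndarray = np.array(
    [b.start_minute for b in BINS] + [BINS[-1].end_minute]
)


class UndefinedProfileError(ValueError):
    """A requested profile variant has no qualifying day (e.g. no active weekend)."""


def bin_index_of_minutes(minutes: np.ndarray) -> np.ndarray:
    """Bin index (0..4, order sleep..night) for minutes-after-midnight values."""
    return np.searchsorted(BIN_EDGES_MINUTES, minutes, side="right") - 1


def bin_of(t: dt.time | dt.datetime) -> TimeBin:
    """The unique bin whose half-open interval contains clock time ``t``."""
    minute = t.hour * 60 + t.minute
    return BINS[int(bin_index_of_minutes(np.array([minute]))[0])]


@dataclasses.dataclass(frozen=True)
class DailyBinCounts:
    participant_id: str
    date: dt.date
    counts: tuple[int, int, int, int, int]
    total: int
    day_type: str  # "weekday" | "weekend"


@dataclasses.dataclass(frozen=True)
class InclusionDecision:
    """Outcome of the 3-of-4 complete-weeks filter for one participant."""

    participant_id: str
    included: bool
    complete_weeks: frozenset[int]
    reason: str


@dataclasses.dataclass
class ParticipantProfile:
    """Averaged five-bin profiles over one participant's included days.

    ``mean_counts`` averages per-day bin counts over every included day
    (zero-total days included); ratio means average per-day ratio vectors
    over days with at least one keystroke (0/0 is undefined).  A weekday or
    weekend variant with no qualifying day is None.
    """

    participant_id: str
    mean_counts: np.ndarray
    mean_ratios: np.ndarray | None
    weekday_mean_ratios: np.ndarray | None
    weekend_mean_ratios: np.ndarray | None
    n_days_used: int
    n_weekdays_used: int
    n_weekend_days_used: int


def _day_frame_skeleton(calendar: StudyCalendar) -> pd.DataFrame:
    dates = calendar.analysis_dates()
    return pd.DataFrame(
        {
            "date": dates,
            "week": [calendar.week_of(d) for d in dates],
            "day_type": ["weekend" if d.weekday() >= 5 else "weekday" for d in dates],
        }
    )


def daily_bin_counts(log: EventLog, calendar: StudyCalendar) -> pd.DataFrame:
    """Per-day five-bin counts for every post-adjustment study date.

    Returns one row per analysis date (zero-count days included) with columns
    ``participant_id, date, sleep..night, total, day_type, week``.  Events
    outside the analysis window are ignored.
    """
    skel = _day_frame_skeleton(calendar)
    counts = np.zeros((len(skel), len(BINS)), dtype=np.int64)
    if len(log):
        press = log.frame["press_time"]
        dates = press.dt.normalize()
        minutes = press.dt.hour.to_numpy() * 60 + press.dt.minute.to_numpy()
        bin_idx = bin_index_of_minutes(minutes)
        date_index = pd.Index(pd.to_datetime(skel["date"]))
        day_idx = date_index.get_indexer(dates)
        in_window = day_idx >= 0
        np.add.at(counts, (day_idx[in_window], bin_idx[in_window]), 1)
    out = skel.copy()
    out.insert(0, "participant_id", log.participant_id)
    for j, label in enumerate(BIN_LABELS):
        out[label] = counts[:, j]
    out["total"] = counts.sum(axis=1)
    return out[["participant_id", "date", *BIN_LABELS, "total", "day_type", "week"]]


def day_records(days: pd.DataFrame) -> Iterator[DailyBinCounts]:
    """Yield one DailyBinCounts record per row of a daily-counts frame."""
    for row in days.itertuples(index=False):
        counts = tuple(int(getattr(row, lbl)) for lbl in BIN_LABELS)
        yield DailyBinCounts(row.participant_id, row.date, counts, int(row.total), row.day_type)


def complete_week_set(
    totals: np.ndarray, weeks: np.ndarray, analysis_weeks: Sequence[int]
) -> set[int]:
    """Weeks whose 7 daily totals are all positive (the completeness unit)."""
    complete: set[int] = set()
    for week in analysis_weeks:
        mask = weeks == week
        if int(mask.sum()) == 7 and bool((totals[mask] > 0).all()):
            complete.add(int(week))
    return complete


def completeness_filter(
    days: pd.DataFrame, calendar: StudyCalendar, min_complete_weeks: int = 3
) -> InclusionDecision:
    """Apply the complete-weeks inclusion rule to one participant's day counts.

    A week is complete iff all 7 of its dates have total > 0; the participant
    is included iff at least ``min_complete_weeks`` analysis weeks are
    complete.
    """
    pid = str(days["participant_id"].iloc[0]) if len(days) else "?"
    complete = complete_week_set(
        days["total"].to_numpy(), days["week"].to_numpy(), calendar.analysis_weeks
    )
    incomplete = [w for w in calendar.analysis_weeks if w not in complete]
    included = len(complete) >= min_complete_weeks
    if included:
        reason = f"{len(complete)} complete weeks {sorted(complete)}"
    else:
        reason = (
            f"only {len(complete)} complete weeks (need >= {min_complete_weeks}); "
            f"incomplete weeks {incomplete}"
        )
    return InclusionDecision(pid, included, frozenset(complete), reason)


def _profile_from_arrays(
    counts: np.ndarray, is_weekend: np.ndarray
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None, np.ndarray | None, int, int, int]:
    """Profile means from a (days, 5) count array; core of participant_profile."""
    n_days = counts.shape[0]
    totals = counts.sum(axis=1)
    mean_counts = counts.mean(axis=0) if n_days else np.zeros(len(BINS))

    def ratio_mean(mask: np.ndarray) -> np.ndarray | None:
        active = mask & (totals > 0)
        if not active.any():
            return None
        sub = counts[active].astype(float)
        return (sub / sub.sum(axis=1, keepdims=True)).mean(axis=0)

    everything = np.ones(n_days, dtype=bool)
    return (
        mean_counts,
        ratio_mean(everything),
        ratio_mean(~is_weekend),
        ratio_mean(is_weekend),
        n_days,
        int((~is_weekend).sum()),
        int(is_weekend.sum()),
    )


def participant_profile(
    days: pd.DataFrame,
    decision: InclusionDecision | None = None,
    ratio_method: str = "per_day",
    strict: bool = False,
) -> ParticipantProfile:
    """Averaged count and ratio profiles over a participant's included days.

    If an inclusion decision is given, only days inside its complete weeks
    enter the averages, so a partially missing week never biases a profile.
    ``ratio_method`` selects how ratio profiles are averaged: ``"per_day"``
    (mean of per-day ratio vectors, the default) or ``"pooled"`` (ratio of
    summed counts).  With ``strict=True`` an undefined weekday/weekend
    variant raises :class:`UndefinedProfileError` instead of being None.
    """
    if ratio_method not in {"per_day", "pooled"}:
        raise ValueError(f"unknown ratio_method {ratio_method!r}")
    pid = str(days["participant_id"].iloc[0]) if len(days) else "?"
    if decision is not None:
        days = days[days["week"].isin(decision.complete_weeks)]
    counts = days[list(BIN_LABELS)].to_numpy(dtype=np.int64)
    is_weekend = (days["day_type"] == "weekend").to_numpy()

    if ratio_method == "pooled":
        totals = counts.sum(axis=1)

        def pooled(mask: np.ndarray) -> np.ndarray | None:
            sub = counts[mask & (totals > 0)]
            if not len(sub):
                return None
            summed = sub.sum(axis=0).astype(float)
            return summed / summed.sum()

        mean_counts = counts.mean(axis=0) if len(counts) else np.zeros(len(BINS))
        parts = (
            mean_counts,
            pooled(np.ones(len(counts), dtype=bool)),
            pooled(~is_weekend),
            pooled(is_weekend),
            len(counts),
            int((~is_weekend).sum()),
            int(is_weekend.sum()),
        )
    else:
        parts = _profile_from_arrays(counts, is_weekend)

    profile = ParticipantProfile(pid, *parts)
    if strict:
        for name in ("mean_ratios", "weekday_mean_ratios", "weekend_mean_ratios"):
            if getattr(profile, name) is None:
                raise UndefinedProfileError(f"participant {pid}: {name} undefined (no active day)")
    return profile


def profiles_frame(profiles: Sequence[ParticipantProfile]) -> pd.DataFrame:
    """Flatten profiles to one row per participant (CSV-ready)."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"participant_id": p.participant_id}
        for j, lbl in enumerate(BIN_LABELS):
            row[f"mean_count_{lbl}"] = p.mean_counts[j]
        for prefix, vec in [
            ("mean_ratio", p.mean_ratios),
            ("weekday_ratio", p.weekday_mean_ratios),
            ("weekend_ratio", p.weekend_mean_ratios),
        ]:
            for j, lbl in enumerate(BIN_LABELS):
                row[f"{prefix}_{lbl}"] = np.nan if vec is None else vec[j]
        row["n_days_used"] = p.n_days_used
        row["n_weekdays_used"] = p.n_weekdays_used
        row["n_weekend_days_used"] = p.n_weekend_days_used
        rows.append(row)
    return pd.DataFrame(rows)
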