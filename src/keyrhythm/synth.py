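"""Synthetic keystroke cohorts with known ground truth.

Each participant's typing is an inhomogeneous Poisson process with a
piecewise-constant daily intensity: five per-bin rates (expected keystrokes
per day), switched between a weekday and a weekend set, and scaled by a
per-participant lognormal activity multiplier that models the large
between-person spread in total typing volume without changing ratio
profiles. Whole days drop out independently with a small probability,
emulating participants who temporarily switch back to another keyboard.
ULS-8 responses are rejection-sampled so every participant's total score
lands inside their group's band.

The shipped default cohort mirrors the study conditions: four loneliness
groups of sizes 18/26/10/5 over a five-week calendar (first week an
adjustment period), evening-peaked weekday profiles that shift toward night
on weekends for the lower-loneliness groups, and a night+sleep-peaked
profile with identical weekday and weekend rates for the very-severe group.
Daily totals of ~3,800-4,600 keystrokes and a lognormal multiplier with
log-scale sd 0.55 put the cohort at a realistic activity scale
(approximately 127,000 keystrokes with a coefficient of variation of 0.6
over the four analysis weeks).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as kio
from .features import BIN_EDGES_MINUTES, BIN_LABELS, _day_frame_skeleton
from .io import EventLog, StudyCalendar
from .uls8 import GROUP_BANDS, GROUP_LABELS, ULS8Response, score_uls8

__all__ = [
    "GroupIntensityProfile",
    "SimCohortConfig",
    "ParticipantTruth",
    "CohortBundle",
    "DEFAULT_GROUP_SIZES",
    "default_calendar",
    "default_profiles",
    "null_profiles",
    "default_config",
    "null_config",
    "generate_participant",
    "generate_uls8",
    "generate_cohort",
    "write_cohort",
]

#: group sizes of the emulated cohort (59 analyzable participants)
DEFAULT_GROUP_SIZES: dict[str, int] = {"no": 18, "moderate": 26, "severe": 10, "very_severe": 5}

#: day-level dropout giving ~10% of participants < 3 complete weeks
DEFAULT_DAY_DROPOUT = 0.022
#: log-scale sd of the per-participant activity multiplier (CV ~ 0.6)
DEFAULT_OVERDISPERSION = 0.55

_DWELL_MS = (40, 250)  # uniform press-to-release dwell


@dataclasses.dataclass(frozen=True)
class GroupIntensityProfile:
    """Ground-truth diurnal intensity for one loneliness group.

    Rates are expected keystrokes per day in each bin (sleep..night) for an
    average participant (multiplier 1).
    """

    label: str
    weekday_rates: tuple[float, ...]
    weekend_rates: tuple[float, ...]
    day_dropout_prob: float = DEFAULT_DAY_DROPOUT
    overdispersion: float = DEFAULT_OVERDISPERSION

    def __post_init__(self) -> None:
        for name in ("weekday_rates", "weekend_rates"):
            rates = np.asarray(getattr(self, name), dtype=float)
            if rates.shape != (len(BIN_LABELS),) or (rates < 0).any():
                raise ValueError(f"{name} must be {len(BIN_LABELS)} nonnegative rates")
        if not 0 <= self.day_dropout_prob < 1:
            raise ValueError("day_dropout_prob must be in [0, 1)")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be nonnegative")


def default_calendar() -> StudyCalendar:
    """Five study weeks starting on a Monday."""
    return StudyCalendar(start_date=dt.date(2023, 3, 6), n_weeks=5, n_adjustment_weeks=1)


def default_profiles() -> dict[str, GroupIntensityProfile]:
    """Per-group intensities mirroring the observed diurnal directions.

    no/moderate/severe: evening-peaked on weekdays, shifted toward night with
    a quieter morning on weekends (weekday != weekend); severe has a lower
    daily total. very_severe: night+sleep-peaked with identical weekday and
    weekend rates (weekday == weekend).
    """
    return {
        "no": GroupIntensityProfile(
            "no", (200, 700, 1100, 1700, 800), (350, 450, 900, 1300, 1500)
        ),
        "moderate": GroupIntensityProfile(
            "moderate", (250, 650, 1050, 1650, 900), (400, 500, 900, 1250, 1450)
        ),
        "severe": GroupIntensityProfile(
            "severe", (250, 600, 900, 1300, 750), (350, 400, 750, 1050, 1250)
        ),
        "very_severe": GroupIntensityProfile(
            "very_severe", (1300, 350, 700, 900, 1350), (1300, 350, 700, 900, 1350)
        ),
    }


def null_profiles() -> dict[str, GroupIntensityProfile]:
    """All four groups share one intensity profile (no group effect)."""
    base = default_profiles()["moderate"]
    return {
        label: dataclasses.replace(base, label=label) for label in GROUP_LABELS
    }


@dataclasses.dataclass
class SimCohortConfig:
    group_sizes: dict[str, int] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    calendar: StudyCalendar = dataclasses.field(default_factory=default_calendar)
    profiles: dict[str, GroupIntensityProfile] = dataclasses.field(
        default_factory=default_profiles
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes.values()):
            raise ValueError("group sizes must be positive")
        missing = set(self.group_sizes) - set(self.profiles)
        if missing:
            raise ValueError(f"profiles missing for groups {sorted(missing)}")


def default_config(seed: int = 0) -> SimCohortConfig:
    return SimCohortConfig(seed=seed)


def scale_intensities(config: SimCohortConfig, factor: float) -> SimCohortConfig:
    """Copy of ``config`` with every per-bin rate multiplied by ``factor``.

    Shrinks cohorts for quick runs without touching shapes, dropout or spread.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    profiles = {
        g: dataclasses.replace(
            p,
            weekday_rates=tuple(r * factor for r in p.weekday_rates),
            weekend_rates=tuple(r * factor for r in p.weekend_rates),
        )
        for g, p in config.profiles.items()
    }
    return dataclasses.replace(config, profiles=profiles)


def null_config(seed: int = 0) -> SimCohortConfig:
    return SimCohortConfig(profiles=null_profiles(), seed=seed)


@dataclasses.dataclass
class ParticipantTruth:
    """Everything the generator drew for one participant."""

    participant_id: str
    group: str
    multiplier: float
    dropped_dates: list[dt.date]
    counts: np.ndarray  # (n calendar days, 5) realized per-bin counts
    uls8_total: int


@dataclasses.dataclass
class CohortBundle:
    config: SimCohortConfig
    logs: dict[str, EventLog | None]
    uls8: dict[str, ULS8Response]
    truths: dict[str, ParticipantTruth]

    @property
    def participant_ids(self) -> list[str]:
        return list(self.truths)

    def day_counts(self, pid: str) -> pd.DataFrame:
        """Daily bin counts over the analysis dates, from the recorded draws.

        Identical to ``features.daily_bin_counts`` applied to the event log
        (each event is placed inside the bin it was drawn for).
        """
        cal = self.config.calendar
        skel = _day_frame_skeleton(cal)
        counts = self.truths[pid].counts[7 * cal.n_adjustment_weeks :]
        out = skel.copy()
        out.insert(0, "participant_id", pid)
        for j, label in enumerate(BIN_LABELS):
            out[label] = counts[:, j]
        out["total"] = counts.sum(axis=1)
        return out[["participant_id", "date", *BIN_LABELS, "total", "day_type", "week"]]


def _events_from_counts(
    pid: str, dates: list[dt.date], counts: np.ndarray, rng: np.random.Generator
) -> EventLog | None:
    """Place each drawn count uniformly (ms resolution) inside its day/bin."""
    n_days, n_bins = counts.shape
    day_idx, bin_idx = np.nonzero(counts)
    reps = counts[day_idx, bin_idx]
    day_rep = np.repeat(day_idx, reps)
    bin_rep = np.repeat(bin_idx, reps)
    n = len(day_rep)
    if n == 0:
        return None
    starts_ms = BIN_EDGES_MINUTES[:-1] * 60_000
    widths_ms = np.diff(BIN_EDGES_MINUTES) * 60_000
    offset_ms = starts_ms[bin_rep] + np.floor(rng.random(n) * widths_ms[bin_rep]).astype(np.int64)
    day0 = np.datetime64(dates[0], "ms")
    press = day0 + day_rep.astype("timedelta64[D]").astype("timedelta64[ms]") + offset_ms.astype(
        "timedelta64[ms]"
    )
    dwell = rng.integers(_DWELL_MS[0], _DWELL_MS[1] + 1, n).astype("timedelta64[ms]")
    frame = pd.DataFrame(
        {"press_time": pd.to_datetime(press), "release_time": pd.to_datetime(press + dwell)}
    )
    return EventLog(pid, frame, source_path=f"synthetic:{pid}")


def generate_participant(
    profile: GroupIntensityProfile,
    calendar: StudyCalendar,
    seed: int | np.random.SeedSequence,
    participant_id: str = "P000",
    events: bool = True,
) -> tuple[EventLog | None, ParticipantTruth]:
    """Draw one participant's keystroke log and its generative ground truth.

    Per calendar day and bin: count ~ Poisson(rate(day type) * multiplier),
    zeroed on dropped days; with ``events=True`` each count is expanded to
    press/release timestamps uniform inside the bin.
    """
    rng = np.random.default_rng(seed)
    od = profile.overdispersion
    # mean-one lognormal multiplier
    multiplier = float(np.exp(rng.normal(-(od**2) / 2.0, od))) if od > 0 else 1.0
    dates = calendar.all_dates()
    is_weekend = np.array([d.weekday() >= 5 for d in dates])
    rates = np.where(
        is_weekend[:, None],
        np.asarray(profile.weekend_rates, dtype=float),
        np.asarray(profile.weekday_rates, dtype=float),
    )
    dropped = rng.random(len(dates)) < profile.day_dropout_prob
    counts = rng.poisson(rates * multiplier)
    counts[dropped] = 0
    truth = ParticipantTruth(
        participant_id=participant_id,
        group=profile.label,
        multiplier=multiplier,
        dropped_dates=[d for d, drop in zip(dates, dropped) if drop],
        counts=counts,
        uls8_total=-1,  # filled in by generate_cohort
    )
    log = _events_from_counts(participant_id, dates, counts, rng) if events else None
    return log, truth


def generate_uls8(group: str, rng: np.random.Generator) -> ULS8Response:
    """Rejection-sample uniform item vectors until the total hits the group band."""
    lo, hi = GROUP_BANDS[group]
    while True:
        r = ULS8Response(tuple(int(v) for v in rng.integers(1, 5, 8)))
        if lo <= score_uls8(r) <= hi:
            return r


def generate_cohort(config: SimCohortConfig, events: bool = True) -> CohortBundle:
    """Generate a full cohort: logs (optional), ULS-8 responses, ground truth.

    Deterministic given ``config.seed``; participant randomness is derived
    from per-participant children of the master seed sequence.
    """
    master = np.random.SeedSequence(config.seed)
    n_total = sum(config.group_sizes.values())
    children = master.spawn(n_total)
    logs: dict[str, EventLog | None] = {}
    uls8: dict[str, ULS8Response] = {}
    truths: dict[str, ParticipantTruth] = {}
    idx = 0
    for group in GROUP_LABELS:
        if group not in config.group_sizes:
            continue
        profile = config.profiles[group]
        for _ in range(config.group_sizes[group]):
            pid = f"P{idx + 1:03d}"
            child = children[idx]
            log, truth = generate_participant(
                profile, config.calendar, child, participant_id=pid, events=events
            )
            # independent stream for the questionnaire
            q_rng = np.random.default_rng(child.spawn(1)[0])
            response = generate_uls8(group, q_rng)
            truth.uls8_total = score_uls8(response)
            logs[pid] = log
            uls8[pid] = response
            truths[pid] = truth
            idx += 1
    return CohortBundle(config, logs, uls8, truths)


def write_cohort(bundle: CohortBundle, outdir: str | Path, format: str = "csv") -> Path:
    """Write a cohort directory: events/*, uls8.csv, calendar.yaml, ground_truth.json."""
    outdir = Path(outdir)
    events_dir = outdir / "events"
    events_dir.mkdir(parents=True, exist_ok=True)
    ext = "jsonl" if format == "jsonl" else "csv"
    for pid, log in bundle.logs.items():
        if log is None:
            continue
        kio.write_event_log(log, events_dir / f"{pid}.{ext}", format=format)
    kio.write_uls8_file(bundle.uls8, outdir / "uls8.csv")
    kio.write_calendar(bundle.config.calendar, outdir / "calendar.yaml")
    truth_json = {
        "seed": bundle.config.seed,
        "group_sizes": bundle.config.group_sizes,
        "profiles": {
            g: {
                "weekday_rates": list(p.weekday_rates),
                "weekend_rates": list(p.weekend_rates),
                "day_dropout_prob": p.day_dropout_prob,
                "overdispersion": p.overdispersion,
            }
            for g, p in bundle.config.profiles.items()
        },
        "participants": {
            pid: {
                "group": t.group,
                "multiplier": t.multiplier,
                "dropped_dates": [d.isoformat() for d in t.dropped_dates],
                "uls8_total": t.uls8_total,
                "bin_counts": t.counts.tolist(),
            }
            for pid, t in bundle.truths.items()
        },
    }
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth_json, fh)
    return outdir
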