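import dataclasses
import datetime as dt

import hypothesis
import pandas as pd
import pytest

from keyrhythm.features import BIN_LABELS, _day_frame_skeleton
from keyrhythm.io import StudyCalendar
from keyrhythm.synth import SimCohortConfig, default_profiles

hypothesis.settings.register_profile(
    "keyrhythm", deadline=None, derandomize=True, max_examples=50
)
hypothesis.settings.load_profile("keyrhythm")


@pytest.fixture
def calendar() -> StudyCalendar:
    # five weeks starting on a Monday
    return StudyCalendar(start_date=dt.date(2023, 3, 6), n_weeks=5, n_adjustment_weeks=1)


def scaled_config(
    seed: int = 0,
    scale: float = 0.05,
    dropout: float | None = None,
    overdispersion: float | None = None,
    **kwargs,
) -> SimCohortConfig:
    """Default cohort shrunk in activity (and optionally group sizes) for fast tests."""
    profiles = {}
    for g, p in default_profiles().items():
        updates = dict(
            weekday_rates=tuple(r * scale for r in p.weekday_rates),
            weekend_rates=tuple(r * scale for r in p.weekend_rates),
        )
        if dropout is not None:
            updates["day_dropout_prob"] = dropout
        if overdispersion is not None:
            updates["overdispersion"] = overdispersion
        profiles[g] = dataclasses.replace(p, **updates)
    return SimCohortConfig(profiles=profiles, seed=seed, **kwargs)


def make_days(calendar: StudyCalendar, counts_by_date: dict, pid: str = "P1") -> pd.DataFrame:
    """Daily-counts frame in the daily_bin_counts schema from {date: 5-tuple}."""
    skel = _day_frame_skeleton(calendar)
    out = skel.copy()
    out.insert(0, "participant_id", pid)
    rows = [counts_by_date.get(d, (0, 0, 0, 0, 0)) for d in out["date"]]
    for j, lbl in enumerate(BIN_LABELS):
        out[lbl] = [r[j] for r in rows]
    out["total"] = out[list(BIN_LABELS)].sum(axis=1)
    return out[["participant_id", "date", *BIN_LABELS, "total", "day_type", "week"]]
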