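import dataclasses

import numpy as np
import pandas as pd
import pytest

from conftest import scaled_config
from keyrhythm.features import BIN_LABELS, daily_bin_counts
from keyrhythm.io import read_calendar, read_event_log, read_uls8_file
from keyrhythm.synth import (
    DEFAULT_GROUP_SIZES,
    GroupIntensityProfile,
    default_calendar,
    default_config,
    generate_cohort,
    generate_participant,
    generate_uls8,
    null_config,
    write_cohort,
)
from keyrhythm.uls8 import GROUP_BANDS, GROUP_LABELS, assign_group, score_uls8


def test_default_cohort_has_study_group_sizes():
    bundle = generate_cohort(default_config(seed=1), events=False)
    by_group = {g: 0 for g in GROUP_LABELS}
    for t in bundle.truths.values():
        by_group[t.group] += 1
    assert by_group == DEFAULT_GROUP_SIZES
    assert len(bundle.truths) == 59


def test_same_seed_bit_identical_different_seed_differs():
    c = scaled_config(seed=7, group_sizes={"no": 2, "severe": 2})
    b1 = generate_cohort(c, events=True)
    b2 = generate_cohort(dataclasses.replace(c, seed=7), events=True)
    b3 = generate_cohort(dataclasses.replace(c, seed=8), events=True)
    for pid in b1.logs:
        pd.testing.assert_frame_equal(b1.logs[pid].frame, b2.logs[pid].frame)
        assert b1.uls8[pid] == b2.uls8[pid]
    assert any(
        not b1.logs[pid].frame.equals(b3.logs[pid].frame) for pid in b1.logs
    )
    assert sorted(t.group for t in b3.truths.values()) == sorted(
        t.group for t in b1.truths.values()
    )


def test_all_rates_zero_yields_empty_log():
    profile = GroupIntensityProfile("no", (0,) * 5, (0,) * 5, 0.0, 0.0)
    log, truth = generate_participant(profile, default_calendar(), seed=0)
    assert log is None
    assert truth.counts.sum() == 0


def test_sleep_only_rates_place_all_events_before_six():
    profile = GroupIntensityProfile("no", (100, 0, 0, 0, 0), (100, 0, 0, 0, 0), 0.0, 0.0)
    cal = default_calendar()
    log, truth = generate_participant(profile, cal, seed=3, participant_id="P1")
    hours = log.frame["press_time"].dt.hour
    assert (hours < 6).all()
    days = daily_bin_counts(log, cal)
    # multiplier is 1 (overdispersion 0): 28-day mean within 3*sqrt(100/28) of 100
    assert abs(days["sleep"].mean() - 100) < 3 * np.sqrt(100 / 28)
    assert (days[["morning", "afternoon", "evening", "night"]].to_numpy() == 0).all()


def test_dwell_is_small_and_positive():
    profile = GroupIntensityProfile("no", (50,) * 5, (50,) * 5, 0.0, 0.0)
    log, _ = generate_participant(profile, default_calendar(), seed=4)
    dwell = (log.frame["release_time"] - log.frame["press_time"]).dt.total_seconds()
    assert (dwell > 0).all() and (dwell < 0.5).all()


def test_dropout_zeroes_recorded_days():
    profile = GroupIntensityProfile("no", (50,) * 5, (50,) * 5, 0.5, 0.0)
    _, truth = generate_participant(profile, default_calendar(), seed=5)
    assert truth.dropped_dates  # p=0.5 over 35 days
    dates = default_calendar().all_dates()
    for d in truth.dropped_dates:
        assert truth.counts[dates.index(d)].sum() == 0


@pytest.mark.parametrize("group", GROUP_LABELS)
def test_uls8_closure_at_volume(group):
    rng = np.random.default_rng(11)
    lo, hi = GROUP_BANDS[group]
    totals = [score_uls8(generate_uls8(group, rng)) for _ in range(250)]
    assert all(lo <= t <= hi for t in totals)
    assert all(assign_group(t).label == group for t in totals)


def test_group_mean_scores_ordered_and_interior():
    rng = np.random.default_rng(12)
    means = {
        g: np.mean([score_uls8(generate_uls8(g, rng)) for _ in range(400)])
        for g in GROUP_LABELS
    }
    assert means["no"] < means["moderate"] < means["severe"] < means["very_severe"]
    for g, (lo, hi) in GROUP_BANDS.items():
        assert lo < means[g] < hi


def test_counts_only_mode_matches_event_mode_draws():
    c = scaled_config(seed=21, group_sizes={"moderate": 3})
    with_events = generate_cohort(c, events=True)
    counts_only = generate_cohort(c, events=False)
    for pid in with_events.truths:
        np.testing.assert_array_equal(
            with_events.truths[pid].counts, counts_only.truths[pid].counts
        )
        assert counts_only.logs[pid] is None


def test_written_cohort_round_trips(tmp_path):
    c = scaled_config(seed=31, group_sizes={"no": 1, "very_severe": 1})
    bundle = generate_cohort(c, events=True)
    outdir = write_cohort(bundle, tmp_path / "cohort", format="jsonl")
    assert read_calendar(outdir / "calendar.yaml") == c.calendar
    uls8 = read_uls8_file(outdir / "uls8.csv")
    assert uls8 == bundle.uls8
    for pid, log in bundle.logs.items():
        back = read_event_log(outdir / "events" / f"{pid}.jsonl")
        pd.testing.assert_frame_equal(back.frame, log.frame)


def test_exclusion_rate_near_study_attrition():
    """Default dropout excludes roughly 10% (the study lost 7 of 66)."""
    from keyrhythm.features import complete_week_set

    cal = default_calendar()
    weeks = np.array([cal.week_of(d) for d in cal.analysis_dates()])
    failures = 0
    n = 0
    for seed in range(5):
        bundle = generate_cohort(default_config(seed=seed), events=False)
        for t in bundle.truths.values():
            totals = t.counts[7:].sum(axis=1)
            if len(complete_week_set(totals, weeks, cal.analysis_weeks)) < 3:
                failures += 1
            n += 1
    rate = failures / n
    assert 0.0 < rate < 0.25
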