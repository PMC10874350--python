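import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_days, scaled_config
from keyrhythm.features import (
    BIN_LABELS,
    BINS,
    UndefinedProfileError,
    bin_of,
    completeness_filter,
    daily_bin_counts,
    day_records,
    participant_profile,
)
from keyrhythm.io import EventLog, KeystrokeEvent
from keyrhythm.synth import generate_cohort


def _log(pid, times):
    return EventLog.from_events(
        [KeystrokeEvent(pid, t, t + dt.timedelta(milliseconds=90)) for t in times]
    )


class TestBinning:
    @pytest.mark.parametrize(
        "clock,label",
        [
            (dt.time(5, 59, 59, 999000), "sleep"),
            (dt.time(6, 0), "morning"),
            (dt.time(11, 59), "morning"),
            (dt.time(12, 0), "afternoon"),
            (dt.time(17, 0), "evening"),
            (dt.time(20, 59), "evening"),
            (dt.time(21, 0), "night"),
            (dt.time(23, 59, 59), "night"),
            (dt.time(0, 0), "sleep"),
        ],
    )
    def test_boundaries(self, clock, label):
        assert bin_of(clock).label == label

    def test_bins_tile_the_day(self):
        minutes = [bin_of(dt.time(m // 60, m % 60)).label for m in range(1440)]
        totals = {lbl: minutes.count(lbl) for lbl in BIN_LABELS}
        assert totals == {"sleep": 360, "morning": 360, "afternoon": 300, "evening": 240, "night": 180}
        assert sum(b.end_minute - b.start_minute for b in BINS) == 1440


class TestDailyBinCounts:
    def test_direct_binning(self, calendar):
        day = calendar.start_date + dt.timedelta(days=8)  # a week-2 date
        times = [dt.datetime.combine(day, dt.time(h)) for h in (1, 7, 22)]
        days = daily_bin_counts(_log("P1", times), calendar)
        row = days[days["date"] == day].iloc[0]
        assert tuple(row[list(BIN_LABELS)]) == (1, 1, 0, 0, 1)
        assert row["total"] == 3

    def test_all_analysis_dates_present_even_when_inactive(self, calendar):
        # only activity is in the adjustment week, which the analysis ignores
        times = [dt.datetime.combine(calendar.start_date, dt.time(10))]
        days = daily_bin_counts(_log("P1", times), calendar)
        assert len(days) == 28
        assert (days["total"] == 0).all()

    def test_conservation_of_events(self, calendar):
        rng = np.random.default_rng(0)
        dates = calendar.analysis_dates()
        times = [
            dt.datetime.combine(rng.choice(dates), dt.time(int(h), int(m)))
            for h, m in zip(rng.integers(0, 24, 200), rng.integers(0, 60, 200))
        ]
        days = daily_bin_counts(_log("P1", times), calendar)
        assert days["total"].sum() == 200
        assert (days[list(BIN_LABELS)].sum(axis=1) == days["total"]).all()

    def test_day_type_matches_weekend(self, calendar):
        days = daily_bin_counts(_log("P1", [dt.datetime.combine(calendar.start_date, dt.time(1))]), calendar)
        for row in day_records(days):
            assert (row.day_type == "weekend") == (row.date.weekday() >= 5)


class TestCompletenessFilter:
    def _one(self, calendar, zero_dates):
        active = {
            d: (1, 1, 1, 1, 1) for d in calendar.analysis_dates() if d not in set(zero_dates)
        }
        return completeness_filter(make_days(calendar, active), calendar)

    def test_full_data_included(self, calendar):
        decision = self._one(calendar, [])
        assert decision.included and decision.complete_weeks == frozenset({2, 3, 4, 5})

    def test_two_incomplete_weeks_excluded(self, calendar):
        zero = [calendar.week_dates(2)[3], calendar.week_dates(3)[6]]
        decision = self._one(calendar, zero)
        assert not decision.included
        assert decision.complete_weeks == frozenset({4, 5})
        assert "2" in decision.reason and "3" in decision.reason

    def test_single_incomplete_week_included(self, calendar):
        decision = self._one(calendar, [calendar.week_dates(2)[0]])
        assert decision.included and decision.complete_weeks == frozenset({3, 4, 5})


class TestParticipantProfile:
    def test_hand_averaged_ratios(self, calendar):
        d1, d2 = calendar.week_dates(2)[0], calendar.week_dates(2)[1]
        days = make_days(calendar, {d1: (1, 1, 1, 1, 1), d2: (0, 0, 0, 0, 5)})
        p = participant_profile(days)
        np.testing.assert_allclose(p.mean_ratios, (0.1, 0.1, 0.1, 0.1, 0.6))

    def test_single_day_identity(self, calendar):
        days = make_days(calendar, {calendar.week_dates(2)[0]: (2, 0, 0, 0, 0)})
        p = participant_profile(days[days["total"] > 0])
        np.testing.assert_allclose(p.mean_counts, (2, 0, 0, 0, 0))
        np.testing.assert_allclose(p.mean_ratios, (1, 0, 0, 0, 0))

    def test_zero_days_enter_count_mean_but_not_ratio_mean(self, calendar):
        d1 = calendar.week_dates(2)[0]
        days = make_days(calendar, {d1: (4, 0, 0, 0, 0)}).head(2)  # one active, one zero day
        p = participant_profile(days)
        np.testing.assert_allclose(p.mean_counts, (2, 0, 0, 0, 0))
        np.testing.assert_allclose(p.mean_ratios, (1, 0, 0, 0, 0))

    def test_day_order_irrelevant(self, calendar):
        rng = np.random.default_rng(3)
        counts = {d: tuple(rng.integers(0, 30, 5)) for d in calendar.analysis_dates()}
        days = make_days(calendar, counts)
        shuffled = days.sample(frac=1, random_state=1)
        a, b = participant_profile(days), participant_profile(shuffled)
        np.testing.assert_allclose(a.mean_ratios, b.mean_ratios)
        np.testing.assert_allclose(a.weekend_mean_ratios, b.weekend_mean_ratios)

    def test_restriction_to_complete_weeks(self, calendar):
        active = {d: (1, 2, 3, 4, 5) for d in calendar.analysis_dates()}
        del active[calendar.week_dates(2)[0]]
        days = make_days(calendar, active)
        decision = completeness_filter(days, calendar)
        p = participant_profile(days, decision)
        assert p.n_days_used == 21  # week 2 dropped entirely

    def test_no_active_weekend_flags_variant(self, calendar):
        weekday_only = {
            d: (1, 1, 1, 1, 1) for d in calendar.analysis_dates() if d.weekday() < 5
        }
        days = make_days(calendar, weekday_only)
        p = participant_profile(days)
        assert p.weekend_mean_ratios is None
        with pytest.raises(UndefinedProfileError):
            participant_profile(days, strict=True)

    def test_pooled_ratio_alternative(self, calendar):
        d1, d2 = calendar.week_dates(2)[0], calendar.week_dates(2)[1]
        days = make_days(calendar, {d1: (1, 1, 1, 1, 1), d2: (0, 0, 0, 0, 5)})
        p = participant_profile(days, ratio_method="pooled")
        np.testing.assert_allclose(p.mean_ratios, (0.1, 0.1, 0.1, 0.1, 0.6))  # 10 events pooled
        with pytest.raises(ValueError):
            participant_profile(days, ratio_method="bogus")

    @given(st.integers(0, 2**31 - 1))
    def test_ratio_profiles_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 50, (14, 5))
        counts[rng.random(14) < 0.3] = 0
        from keyrhythm.features import _profile_from_arrays

        _, ratios, wk, we, *_ = _profile_from_arrays(counts, np.arange(14) % 7 >= 5)
        for vec in (ratios, wk, we):
            if vec is not None:
                assert abs(vec.sum() - 1.0) < 1e-9
                assert ((vec >= 0) & (vec <= 1)).all()


def test_counts_match_generator_draws_exactly(calendar):
    # generated events, once binned, reproduce the generator's recorded Poisson draws
    import dataclasses

    config = scaled_config(seed=4, group_sizes={"no": 2, "very_severe": 2})
    config = dataclasses.replace(config)
    bundle = generate_cohort(config, events=True)
    for pid, log in bundle.logs.items():
        days = daily_bin_counts(log, bundle.config.calendar)
        expected = bundle.truths[pid].counts[7:]
        assert (days[list(BIN_LABELS)].to_numpy() == expected).all()


def test_cohort_mean_counts_converge_to_intensities():
    # 200 participants x 28 days: per-bin mean counts within 3 empirical SEs of the rates
    config = scaled_config(seed=9, scale=0.1, dropout=0.0, group_sizes={"no": 200})
    bundle = generate_cohort(config, events=False)
    rates_wd = np.array(config.profiles["no"].weekday_rates)
    means = []
    for pid in bundle.participant_ids:
        days = bundle.day_counts(pid)
        wd = days[days["day_type"] == "weekday"]
        means.append(wd[list(BIN_LABELS)].mean(axis=0).to_numpy())
    means = np.array(means)
    se = means.std(axis=0, ddof=1) / np.sqrt(len(means))
    assert (np.abs(means.mean(axis=0) - rates_wd) < 3 * se + 1e-9).all()
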