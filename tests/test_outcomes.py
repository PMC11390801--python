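"""Outcome rates and the antibiotic-episode segmentation rule."""

import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nascher import compute_outcome_rates, count_antibiotic_episodes, summarize_distribution
from nascher.cohort import Cohort


def brute_force_episodes(day_numbers) -> int:
    """Independent day-scan oracle: walk the calendar, count maximal runs
    not interrupted by >= 2 consecutive antibiotic-free days."""
    days = sorted(set(day_numbers))
    if not days:
        return 0
    episodes, free = 1, 0
    for d in range(days[0] + 1, days[-1] + 1):
        if d in set(days):
            if free >= 2:
                episodes += 1
            free = 0
        else:
            free += 1
    return episodes


def to_dates(day_numbers):
    base = datetime.date(2021, 1, 1)
    return [base + datetime.timedelta(days=int(d)) for d in day_numbers]


class TestEpisodeCounting:
    @pytest.mark.parametrize(
        "days, expected",
        [
            ([], 0),
            ([1, 2, 3, 6], 2),  # days 4,5 free -> two episodes
            ([1, 3], 1),  # single free day continues the episode
            ([1, 4], 2),  # two free days split
            ([5], 1),
        ],
    )
    def test_hand_checked_cases(self, days, expected):
        assert count_antibiotic_episodes(to_dates(days)) == expected
        assert brute_force_episodes(days) == expected

    def test_duplicates_and_order_irrelevant(self):
        days = [7, 1, 2, 2, 7, 10, 1]
        assert count_antibiotic_episodes(to_dates(days)) == count_antibiotic_episodes(
            to_dates(sorted(set(days)))
        )

    @given(st.sets(st.integers(0, 60), max_size=25))
    def test_matches_day_scan_oracle(self, days):
        assert count_antibiotic_episodes(to_dates(days)) == brute_force_episodes(days)

    @given(st.sets(st.integers(0, 60), max_size=25))
    def test_episodes_bounded_by_distinct_days(self, days):
        assert count_antibiotic_episodes(to_dates(days)) <= len(days)


def one_resident_cohort(obs_days, events):
    base = datetime.date(2021, 1, 1)
    residents = pd.DataFrame(
        {
            "resident_id": ["R1"],
            "sex": ["female"],
            "age_years": [80.0],
            "care_level": [4],
            "admission_date": [pd.Timestamp(base)],
            "end_date": [pd.Timestamp(base + datetime.timedelta(days=obs_days - 1))],
            "end_reason": ["still_resident"],
        }
    )
    ev = pd.DataFrame(
        {
            "resident_id": "R1",
            "event_type": [t for t, _ in events],
            "event_date": pd.to_datetime([base + datetime.timedelta(days=d) for _, d in events]),
        }
    )
    endo = pd.DataFrame({"resident_id": [], "item_name": [], "endorsed": []})
    return Cohort(residents, endo, ev).validate()


class TestOutcomeRates:
    def test_yearly_normalization(self):
        cohort = one_resident_cohort(731, [("medication_change", d) for d in range(10)])
        rates = compute_outcome_rates(cohort)
        assert rates.loc["R1", "med_changes_per_year"] == pytest.approx(10 * 365.25 / 731)

    def test_weekly_normalization(self):
        cohort = one_resident_cohort(14, [("doctor_documentation", d) for d in range(4)])
        rates = compute_outcome_rates(cohort)
        assert rates.loc["R1", "documentations_per_week"] == pytest.approx(2.0)

    def test_no_events_all_zero(self):
        rates = compute_outcome_rates(one_resident_cohort(100, []))
        assert (rates.loc["R1", list(rates.columns[1:])] == 0).all()

    def test_rates_scale_linearly_in_counts(self):
        ev = [("medication_change", d) for d in (3, 5, 9)]
        single = compute_outcome_rates(one_resident_cohort(50, ev))
        double = compute_outcome_rates(one_resident_cohort(50, ev + ev))
        assert double.loc["R1", "med_changes_per_year"] == pytest.approx(
            2 * single.loc["R1", "med_changes_per_year"]
        )

    def test_same_day_repeats_each_count(self):
        # duplicate medication changes on one day are separate events
        ev = [("medication_change", 4), ("medication_change", 4)]
        rates = compute_outcome_rates(one_resident_cohort(10, ev))
        assert rates.loc["R1", "n_med_changes"] == 2


class TestSummarizeDistribution:
    def test_symmetric_sample_has_zero_skewness(self):
        s = summarize_distribution([1, 2, 3, 4, 5])
        assert s["skewness"] == pytest.approx(0.0)
        assert s["median"] == 3 and s["mean"] == 3

    def test_constant_sample_degenerates(self):
        s = summarize_distribution([4.0, 4.0, 4.0, 4.0])
        assert s["sd"] == 0.0
        assert np.isnan(s["skewness"]) and np.isnan(s["excess_kurtosis"])

    def test_normal_sample_near_zero_skew_and_kurtosis(self):
        draws = np.random.default_rng(42).standard_normal(10_000)
        s = summarize_distribution(draws)
        assert abs(s["skewness"]) < 0.1
        assert abs(s["excess_kurtosis"]) < 0.1

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            summarize_distribution([1.0])

    def test_nearest_rank_quartiles(self):
        s = summarize_distribution([1, 2, 3, 4])
        assert (s["q1"], s["q3"]) == (1, 3)
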