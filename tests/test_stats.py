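"""Correlation, contingency, k-sample, Kaplan-Meier and Cox machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from nascher.errors import ConvergenceError
from nascher.stats import (
    build_survival_records,
    chi_square_test,
    cox_fit,
    km_estimate,
    kruskal_wallis,
    median_split,
    spearman,
)


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3], [1, 2, 3])["rho"] == pytest.approx(1.0)

    def test_hand_computed_rho(self):
        # d^2 = (4, 1, 1): rho = 1 - 6*6 / (3*8) = -0.5
        assert spearman([1, 2, 3], [3, 1, 2])["rho"] == pytest.approx(-0.5)

    def test_ties_use_midranks(self):
        x, y = [1, 1, 2, 4, 4, 5], [1, 2, 3, 3, 5, 6]
        mid = sps.pearsonr(sps.rankdata(x), sps.rankdata(y)).statistic
        assert spearman(x, y)["rho"] == pytest.approx(mid)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([2, 2, 2], [1, 2, 3])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(40), rng.random(40)
        base = spearman(x, y)["rho"]
        assert spearman(np.exp(3 * x), y)["rho"] == pytest.approx(base)
        assert spearman(x, y**3)["rho"] == pytest.approx(base)


class TestChiSquare:
    def test_independence_gives_zero(self):
        res = chi_square_test([[10, 10], [10, 10]])
        assert res["statistic"] == pytest.approx(0.0)

    def test_hand_computed_statistic(self):
        res = chi_square_test([[20, 10], [10, 20]])
        assert res["statistic"] == pytest.approx(20 / 3)
        assert res["df"] == 1

    def test_zero_expected_count_rejected(self):
        with pytest.raises(ValueError):
            chi_square_test([[5, 0], [7, 0]])


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([1, 1, 1], [1, 1, 1], [1, 1])
        assert res["statistic"] == 0.0

    def test_perfect_separation_matches_rank_sum_formula(self):
        groups = [[1, 2], [3, 4], [5, 6]]
        n = 6
        mean_ranks = [1.5, 3.5, 5.5]
        h = 12 / (n * (n + 1)) * sum(2 * (r - (n + 1) / 2) ** 2 for r in mean_ranks)
        assert kruskal_wallis(*groups)["statistic"] == pytest.approx(h)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2, 3, 4, 5])


class TestMedianSplit:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([1, 2, 3], [False, False, True]),
            ([5, 5, 5, 5], [False, False, False, False]),
            ([3, 3, 4, 5], [False, False, True, True]),  # median 3.5
        ],
    )
    def test_strictly_above_median(self, values, expected):
        assert list(median_split(values)) == expected


class TestKaplanMeier:
    def test_product_limit_by_hand(self):
        r = km_estimate([1, 2, 3], [True, True, True])
        assert r.survival_function["survival"].tolist() == pytest.approx(
            [1.0, 2 / 3, 1 / 3, 0.0]
        )
        assert r.median_days == 2

    def test_all_censored_curve_stays_at_one(self):
        r = km_estimate([5, 6, 7], [False, False, False])
        assert r.median_days is None
        assert (r.survival_function["survival"] == 1.0).all()

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(11)
        times = rng.integers(1, 50, size=200)
        r = km_estimate(times, np.ones(200, bool))
        for t in [1, 5, 10, 25, 49]:
            assert float(r.survival_function.loc[t, "survival"]) == pytest.approx(
                np.mean(times > t)
            )

    def test_exponential_median_recovery(self):
        rng = np.random.default_rng(5)
        times = rng.exponential(100 / np.log(2), size=5000)
        r = km_estimate(times, np.ones(5000, bool))
        assert 90 <= r.median_days <= 110

    def test_curve_monotone_from_one(self, ten_cohorts):
        cohort, _ = ten_cohorts[0]
        days = cohort.observation_days()
        event = cohort.residents.set_index("resident_id")["end_reason"].str.startswith("died")
        r = km_estimate(days.to_numpy(), event.reindex(days.index).to_numpy())
        surv = r.survival_function["survival"].to_numpy()
        assert surv[0] == 1.0
        assert (np.diff(surv) <= 1e-12).all()


def simulate_survival_frame(rng, n, hr=1.0, censor_at=None):
    x = rng.random(n) < 0.5
    t = rng.exponential(1.0 / (0.01 * np.where(x, hr, 1.0)))
    event = np.ones(n, bool)
    if censor_at is not None:
        event = t <= censor_at
        t = np.minimum(t, censor_at)
    return pd.DataFrame(
        {
            "time_days": np.maximum(1, np.ceil(t)),
            "event": event,
            "covariate": x.astype(float),
        }
    )


class TestCox:
    def test_null_covariate_hr_near_one(self):
        hrs = []
        for seed in range(20):
            df = simulate_survival_frame(np.random.default_rng(seed), 200)
            hrs.append(cox_fit(df, terms=["covariate"]).hazard_ratio("covariate"))
        assert 0.8 <= np.exp(np.mean(np.log(hrs))) <= 1.25

    def test_recovers_planted_hazard_ratio(self):
        rng = np.random.default_rng(123)
        t80 = 160.0  # ~80th percentile of the mixture
        df = simulate_survival_frame(rng, 2000, hr=3.0, censor_at=t80)
        hr = cox_fit(df, terms=["covariate"]).hazard_ratio("covariate")
        assert 2.6 <= hr <= 3.4

    def test_separation_raises_convergence_error(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {
                "time_days": rng.integers(1, 100, 120).astype(float),
                "event": rng.random(120) < 0.5,
            }
        )
        df["covariate"] = df["event"].astype(float)  # perfectly separates
        with pytest.raises(ConvergenceError):
            cox_fit(df, terms=["covariate"])

    def test_too_few_events_raises(self):
        df = pd.DataFrame(
            {"time_days": [3.0, 4.0, 5.0], "event": [True, False, False], "covariate": [0.0, 1.0, 1.0]}
        )
        with pytest.raises(ConvergenceError):
            cox_fit(df, terms=["covariate"])


class TestSurvivalRecords:
    def test_reference_levels_and_event_coding(self, ten_cohorts, gen_params):
        from nascher import PAPER_BOUNDARIES, load_config, score_cohort

        cohort, truth = ten_cohorts[0]
        scores = score_cohort(cohort, load_config("revised"), strict=False)
        rec = build_survival_records(cohort, scores, PAPER_BOUNDARIES["revised"])
        assert set(rec["category"]) <= {"lowest", "middle", "highest"}
        died = cohort.residents.set_index("resident_id")["end_reason"].isin(
            {"died_in_facility", "died_in_hospital"}
        )
        assert (rec["event"] == died.reindex(rec.index)).all()
        # median split: at-or-below-median ages are the reference (False)
        ages = cohort.residents["age_years"].astype(float)
        assert rec["age_above_median"].to_numpy().sum() == (ages > ages.median()).sum()
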