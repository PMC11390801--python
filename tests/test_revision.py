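"""The three-step score revision: pruning, direction, two-tier weights."""

import math

import numpy as np
import pandas as pd
import pytest

from nascher import RevisionThresholds, derive_revised_config, item_prevalence
from nascher.cohort import Cohort
from nascher.outcomes import OUTCOME_RATE_COLUMNS
from nascher.revision import item_outcome_associations
from nascher.scoring import ScoreConfig, ScoreItem
from nascher.simulate import CountParams, GeneratorParams, ItemParams, generate_cohort
from nascher.calibrate import solve_item_intercept


def config_of(names, points=1):
    return ScoreConfig("test", tuple(ScoreItem(n, points) for n in names))


def cohort_with_endorsements(n, endorsed_by_item):
    residents = pd.DataFrame(
        {
            "resident_id": [f"P{i}" for i in range(n)],
            "sex": "female",
            "age_years": 80.0,
            "care_level": 4,
            "admission_date": pd.Timestamp("2021-01-01"),
            "end_date": pd.Timestamp("2021-12-31"),
            "end_reason": "still_resident",
        }
    )
    rows = [
        (f"P{i}", item, 1)
        for item, holders in endorsed_by_item.items()
        for i in holders
    ]
    endo = pd.DataFrame(rows, columns=["resident_id", "item_name", "endorsed"])
    ev = pd.DataFrame({"resident_id": [], "event_type": [], "event_date": []})
    return Cohort(residents, endo, ev).validate()


class TestItemPrevalence:
    def test_universal_item(self):
        cohort = cohort_with_endorsements(2, {"a": [0, 1]})
        assert item_prevalence(cohort, config_of(["a"]))["a"] == 1.0

    def test_quarter_prevalence_counts_missing_rows_as_unendorsed(self):
        cohort = cohort_with_endorsements(4, {"a": [2]})
        assert item_prevalence(cohort, config_of(["a", "b"]))["a"] == 0.25
        assert item_prevalence(cohort, config_of(["a", "b"]))["b"] == 0.0


def rates_frame(ids, values):
    df = pd.DataFrame({c: values for c in OUTCOME_RATE_COLUMNS}, index=pd.Index(ids, name="resident_id"))
    df.insert(0, "observation_days", 365)
    return df


class TestAssociations:
    def test_positive_by_construction(self):
        n = 30
        cohort = cohort_with_endorsements(n, {"a": range(20, 30)})  # top raters hold it
        rates = rates_frame([f"P{i}" for i in range(n)], np.arange(n, dtype=float))
        (assoc,) = item_outcome_associations(cohort, config_of(["a"]), rates)
        for rho, p in assoc.per_outcome.values():
            assert rho > 0 and 0 <= p < 1

    def test_zero_variance_item_is_undefined(self):
        n = 10
        cohort = cohort_with_endorsements(n, {"a": range(n)})
        rates = rates_frame([f"P{i}" for i in range(n)], np.arange(n, dtype=float))
        (assoc,) = item_outcome_associations(cohort, config_of(["a"]), rates)
        assert all(math.isnan(rho) for rho, _ in assoc.per_outcome.values())
        assert assoc.n_significant_positive(0.05) == 0

    def test_independent_item_uncorrelated_on_average(self):
        rng = np.random.default_rng(9)
        rhos = []
        n = 1000
        ids = [f"P{i}" for i in range(n)]
        for _ in range(100):
            cohort = cohort_with_endorsements(
                n, {"a": np.flatnonzero(rng.random(n) < 0.4)}
            )
            rates = rates_frame(ids, rng.random(n))
            (assoc,) = item_outcome_associations(cohort, config_of(["a"]), rates)
            rhos.append(assoc.per_outcome[OUTCOME_RATE_COLUMNS[0]][0])
        assert abs(np.mean(rhos)) < 0.05


def planted_params(loadings, prevalences, scoring_config_path, n=396):
    """Bespoke generator over an eight-item checklist with planted tiers."""
    items = {
        name: ItemParams(solve_item_intercept(prevalences[name], loadings[name]), loadings[name])
        for name in loadings
    }
    counts = {
        "med_changes": CountParams(np.log(16.0), 0.8, 0.7, 365.25),
        "documentations": CountParams(np.log(1.8), 0.6, 2.0, 7.0),
        "antibiotic_episodes": CountParams(np.log(1.5), 0.7, 0.9, 365.25),
    }
    return GeneratorParams(
        n_residents=n,
        item_params=items,
        count_params=counts,
        scoring_config=str(scoring_config_path),
    )


@pytest.mark.parametrize("seed", [0])
def test_planted_tiers_recovered_by_majority_vote(seed, tmp_path):
    """Strong items get 2 points, weak 1 point; inverse and rare items are
    removed — by majority over 50 simulated cohorts."""
    loadings = {"A": 1.5, "B": 1.5, "C": 0.15, "D": 0.15, "E": 0.15, "F": 0.15, "G": -1.2, "H": 0.0}
    prevalences = {"A": 0.5, "B": 0.35, "C": 0.6, "D": 0.45, "E": 0.3, "F": 0.55, "G": 0.4, "H": 0.02}
    base = config_of(list(loadings))
    cfg_path = base.to_yaml(tmp_path / "planted.yaml")
    params = planted_params(loadings, prevalences, cfg_path)
    tally = {name: {"two": 0, "one": 0, "rare": 0, "inverse": 0} for name in loadings}
    for s in range(seed, seed + 50):
        cohort = generate_cohort(params, seed=s)
        rep = derive_revised_config(cohort, base)
        for name in loadings:
            if name in rep.two_point_items:
                tally[name]["two"] += 1
            elif name in rep.one_point_items:
                tally[name]["one"] += 1
            elif name in rep.removed_rare:
                tally[name]["rare"] += 1
            else:
                tally[name]["inverse"] += 1
        # partition invariant: the four sets cover the base config exactly
        all_items = (
            set(rep.removed_rare) | set(rep.removed_inverse)
            | set(rep.two_point_items) | set(rep.one_point_items)
        )
        assert all_items == set(loadings)
    majority = {name: max(t, key=t.get) for name, t in tally.items()}
    assert majority["A"] == "two" and majority["B"] == "two"
    assert all(majority[k] == "one" for k in "CDEF")
    assert majority["G"] == "inverse"
    assert majority["H"] == "rare"


class TestDeriveRevisedConfig:
    def test_zero_prevalence_item_removed(self):
        cohort = cohort_with_endorsements(20, {"a": range(10), "b": []})
        # give outcomes some spread so associations are computable
        cohort.events = pd.DataFrame(
            {
                "resident_id": [f"P{i}" for i in range(20) for _ in range(i % 5)],
                "event_type": "medication_change",
                "event_date": pd.Timestamp("2021-06-01"),
            }
        )
        rep = derive_revised_config(cohort, config_of(["a", "b"]))
        assert rep.removed_rare == ["b"]

    def test_deterministic_given_cohort(self, ten_cohorts):
        from nascher import load_config

        cohort, _ = ten_cohorts[0]
        base = load_config("original")
        r1 = derive_revised_config(cohort, base)
        r2 = derive_revised_config(cohort, base)
        assert r1.to_dict() == r2.to_dict()

    def test_points_are_two_tier_and_subset(self, ten_cohorts):
        from nascher import load_config

        cohort, _ = ten_cohorts[1]
        base = load_config("original")
        rep = derive_revised_config(cohort, base)
        assert set(rep.config.item_names) <= set(base.item_names)
        assert {it.points for it in rep.config.items} <= {1, 2}

    def test_tie_consistency_identical_items(self):
        # every item endorsed by exactly the same residents: identical
        # associations, so either all get 2 points or none do
        holders = list(range(0, 200, 2))
        cohort = cohort_with_endorsements(200, {k: holders for k in "abc"})
        rng = np.random.default_rng(4)
        ids = [f"P{i}" for i in range(200)]
        rates = rates_frame(ids, rng.random(200) + 2.0 * np.isin(np.arange(200), holders))
        rep = derive_revised_config(cohort, config_of(["a", "b", "c"]), outcome_rates=rates)
        assert rep.two_point_items in ([], ["a", "b", "c"])

    def test_custom_thresholds_respected(self, ten_cohorts):
        from nascher import load_config

        cohort, _ = ten_cohorts[0]
        strict = derive_revised_config(
            cohort, load_config("original"), RevisionThresholds(min_prevalence=0.5)
        )
        assert all(
            item in strict.removed_rare
            for item, prev in item_prevalence(cohort, load_config("original")).items()
            if prev < 0.5
        )
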