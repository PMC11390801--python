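"""Shared fixtures: a hand-built miniature cohort and the ten default
synthetic cohorts used by the calibration and recovery checks."""

import datetime

import pandas as pd
import pytest
from hypothesis import settings

from nascher import default_params, generate_cohort_with_truth
from nascher.cohort import Cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

ACCEPTANCE_SEEDS = tuple(range(1, 11))


def make_tiny_cohort() -> Cohort:
    """Two residents, four endorsements, five events — all hand-checked."""
    residents = pd.DataFrame(
        {
            "resident_id": ["A1", "B2"],
            "sex": ["female", "male"],
            "age_years": [84.5, 79.0],
            "care_level": [4, 5],
            "admission_date": pd.to_datetime(["2021-01-01", "2021-06-15"]),
            "end_date": pd.to_datetime(["2021-12-31", "2021-06-28"]),
            "end_reason": ["still_resident", "died_in_facility"],
        }
    )
    endorsements = pd.DataFrame(
        {
            "resident_id": ["A1", "A1", "B2", "B2"],
            "item_name": [
                "geriatric_patient",
                "risk_of_falls",
                "geriatric_patient",
                "malnutrition",
            ],
            "endorsed": [1, 1, 1, 1],
        }
    )
    events = pd.DataFrame(
        {
            "resident_id": ["A1", "A1", "A1", "B2", "B2"],
            "event_type": [
                "medication_change",
                "doctor_documentation",
                "antibiotic_administration",
                "medication_change",
                "antibiotic_administration",
            ],
            "event_date": pd.to_datetime(
                ["2021-02-01", "2021-03-01", "2021-04-01", "2021-06-20", "2021-06-21"]
            ),
        }
    )
    return Cohort(residents=residents, endorsements=endorsements, events=events).validate()


@pytest.fixture
def tiny_cohort() -> Cohort:
    return make_tiny_cohort()


@pytest.fixture(scope="session")
def gen_params():
    return default_params()


@pytest.fixture(scope="session")
def ten_cohorts(gen_params):
    """(Cohort, truth) for the ten default synthetic cohorts, seeds 1-10."""
    return [generate_cohort_with_truth(gen_params, seed=s) for s in ACCEPTANCE_SEEDS]


@pytest.fixture(scope="session")
def cohort_seed1(ten_cohorts) -> Cohort:
    return ten_cohorts[0][0]
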