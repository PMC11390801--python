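"""Medical-needs outcome operationalization.

Three per-resident outcomes quantify medical effort over the
observation window:

* medication changes per year,
* ward-doctor documentations per week,
* acute illnesses treated with antibiotics per year.

The third is counted as *antibiotic episodes*: a maximal run of
antibiotic-administration days not interrupted by at least two
consecutive antibiotic-free days.  Rates are normalized per resident by
the observation window (365.25 days per year, 7 days per week).
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, observation_days_series
from .scoring import nearest_rank_quantile

DAYS_PER_YEAR = 365.25
DAYS_PER_WEEK = 7.0

OUTCOME_RATE_COLUMNS = (
    "med_changes_per_year",
    "documentations_per_week",
    "antibiotic_episodes_per_year",
)


def count_antibiotic_episodes(administration_dates: Iterable) -> int:
    """Number of antibiotic episodes in a set of administration dates.

    Consecutive or one-day-apart administrations continue an episode; a
    gap of at least three days between successive administrations (i.e.
    at least two whole antibiotic-free days) starts a new one.
    Duplicate dates and input order are irrelevant.
    """
    dates = pd.to_datetime(pd.Series(list(administration_dates)))
    if dates.empty:
        return 0
    ordinals = np.unique(dates.map(pd.Timestamp.toordinal).to_numpy())
    gaps = np.diff(ordinals)
    return 1 + int(np.count_nonzero(gaps >= 3))


def compute_outcome_rates(cohort: Cohort) -> pd.DataFrame:
    """Per-resident outcome counts and window-normalized rates.

    Returns a DataFrame indexed by resident_id with the raw counts
    (``n_med_changes``, ``n_documentations``, ``n_antibiotic_episodes``),
    the observation window length, and the three normalized rates.
    Medication changes and documentations are row counts (repeated
    same-day events each count); antibiotic administrations are
    segmented into episodes first.
    """
    days = observation_days_series(cohort.residents)
    ev = cohort.events
    by_type = {
        t: ev[ev["event_type"] == t]
        for t in ("medication_change", "doctor_documentation", "antibiotic_administration")
    }
    n_med = by_type["medication_change"].groupby("resident_id").size()
    n_doc = by_type["doctor_documentation"].groupby("resident_id").size()
    abx = by_type["antibiotic_administration"]
    n_epi = abx.groupby("resident_id")["event_date"].agg(count_antibiotic_episodes)

    out = pd.DataFrame(index=days.index)
    out.index.name = "resident_id"
    out["observation_days"] = days
    out["n_med_changes"] = n_med.reindex(out.index, fill_value=0).astype(int)
    out["n_documentations"] = n_doc.reindex(out.index, fill_value=0).astype(int)
    out["n_antibiotic_episodes"] = n_epi.reindex(out.index, fill_value=0).astype(int)
    out["med_changes_per_year"] = out["n_med_changes"] * DAYS_PER_YEAR / out["observation_days"]
    out["documentations_per_week"] = (
        out["n_documentations"] * DAYS_PER_WEEK / out["observation_days"]
    )
    out["antibiotic_episodes_per_year"] = (
        out["n_antibiotic_episodes"] * DAYS_PER_YEAR / out["observation_days"]
    )
    return out


def summarize_distribution(values) -> dict:
    """Descriptive summary: mean, SD, median, nearest-rank quartiles,
    range, and bias-corrected sample skewness / excess kurtosis.

    Skewness and excess kurtosis use the bias-corrected sample formulas
    under which a normal distribution has expectation 0 for both; they
    are reported as NaN for fewer than 4 values or a zero-variance
    sample.  Raises ``ValueError`` for fewer than 2 values (dispersion
    undefined).
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size < 2:
        raise ValueError("need at least 2 values to summarize dispersion")
    sd = float(np.std(arr, ddof=1))
    if arr.size >= 4 and sd > 0:
        skew = float(stats.skew(arr, bias=False))
        kurt = float(stats.kurtosis(arr, fisher=True, bias=False))
    else:
        skew = kurt = math.nan
    return {
        "n": int(arr.size),
        "mean": float(np.mean(arr)),
        "sd": sd,
        "median": float(np.median(arr)),
        "q1": float(nearest_rank_quantile(arr, 0.25)),
        "q3": float(nearest_rank_quantile(arr, 0.75)),
        "min": float(np.min(arr)),
        "max": float(np.max(arr)),
        "skewness": skew,
        "excess_kurtosis": kurt,
    }
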