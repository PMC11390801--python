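"""Statistical battery: rank correlation, contingency and k-sample
tests, Kaplan-Meier estimation, and adjusted Cox proportional-hazards
regression.

Standard tests are delegated to scipy.stats; survival estimation to
lifelines (Kaplan-Meier with log-log Greenwood confidence bands, Cox
partial likelihood with Efron tie handling — day-granularity data
produce many tied event times).  Death (in the facility or after
transfer to hospital) is the event; discharge and the administrative
cutoff censor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergenceError
from lifelines.utils import median_survival_times
from scipy import stats as sps

from .cohort import DEATH_REASONS, Cohort, observation_days_series
from .errors import ConvergenceError
from .scoring import CategoryBoundaries, categorize_series


def spearman(x, y) -> dict:
    """Spearman rank correlation with average ranks for ties; two-sided
    p-value from the t approximation.  Raises ``ValueError`` on constant
    input (correlation undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length samples of size >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: rank correlation undefined")
    rho, p = sps.spearmanr(x, y)
    return {"rho": float(rho), "p_value": float(p)}


def chi_square_test(contingency_table) -> dict:
    """Pearson chi-square test of independence, no continuity correction."""
    table = np.asarray(contingency_table, dtype=float)
    if table.ndim != 2:
        raise ValueError("contingency table must be two-dimensional")
    res = sps.chi2_contingency(table, correction=False)
    if np.any(res.expected_freq <= 0):
        raise ValueError("zero expected count in contingency table")
    return {"statistic": float(res.statistic), "p_value": float(res.pvalue), "df": int(res.dof)}


def kruskal_wallis(*groups) -> dict:
    """Kruskal-Wallis H test (tie-corrected) across k >= 2 groups."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    if sum(a.size for a in arrays) < 5:
        raise ValueError("need total n >= 5")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):  # identical groups: H is 0 by convention
        return {"statistic": 0.0, "p_value": 1.0}
    stat, p = sps.kruskal(*arrays)
    return {"statistic": float(stat), "p_value": float(p)}


def median_split(values) -> np.ndarray:
    """True for values strictly above the sample median.

    The at-or-below-median group is the reference level in the adjusted
    survival models, so ties with the median land in the reference.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values for a median split")
    return arr > np.median(arr)


@dataclass
class KMResult:
    """Product-limit survival curve with median survival time.

    ``median_days`` is the smallest time at which the curve drops to
    0.5 or below; ``None`` means the curve never reaches 0.5 — survival
    beyond the observation period.  The 95% CI for the median comes from
    where the log-log Greenwood confidence band crosses 0.5
    (Brookmeyer-Crowley style); non-finite bounds are reported as None.
    """

    survival_function: pd.DataFrame
    median_days: Optional[float]
    median_ci: tuple[Optional[float], Optional[float]]
    n: int
    n_events: int


def km_estimate(time_days, event) -> KMResult:
    """Kaplan-Meier estimate of the survival function for one group."""
    time = np.asarray(time_days, dtype=float)
    ev = np.asarray(event, dtype=bool)
    if time.size == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=ev)
    median = kmf.median_survival_time_
    median = None if np.isinf(median) else float(median)
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = float(ci.iloc[0, 0]), float(ci.iloc[0, 1])
    sf = kmf.survival_function_.rename(columns={"KM_estimate": "survival"})
    return KMResult(
        survival_function=sf,
        median_days=median,
        median_ci=(None if np.isinf(lo) else lo, None if np.isinf(hi) else hi),
        n=int(time.size),
        n_events=int(ev.sum()),
    )


def build_survival_records(
    cohort: Cohort, scores: pd.Series, boundaries: CategoryBoundaries
) -> pd.DataFrame:
    """Assemble the survival analysis table.

    One row per resident: observation time in days, death indicator,
    score category at the given boundaries, and the adjusted covariates
    (sex, age and care level dichotomized at their sample medians).
    """
    res = cohort.residents
    ids = res["resident_id"].to_numpy()
    records = pd.DataFrame(index=pd.Index(ids, name="resident_id"))
    records["time_days"] = observation_days_series(res).to_numpy()
    records["event"] = res["end_reason"].isin(DEATH_REASONS).to_numpy()
    records["category"] = categorize_series(scores.reindex(ids), boundaries).to_numpy()
    records["male"] = (res["sex"] == "male").to_numpy()
    records["age_above_median"] = median_split(res["age_years"].astype(float))
    records["care_above_median"] = median_split(res["care_level"].astype(float))
    return records


@dataclass
class CoxResult:
    """Adjusted proportional-hazards estimates.

    ``table`` has one row per non-reference covariate level with the
    hazard ratio, Wald 95% CI, and p-value.  Reference levels: lowest
    score category, female, at-or-below-median age, at-or-below-median
    care level.
    """

    table: pd.DataFrame
    n: int
    n_events: int
    log_likelihood: float

    def hazard_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "hazard_ratio"])


#: Dummy coding applied to the survival records before the Cox fit.
_COX_TERMS = {
    "category_middle": lambda df: (df["category"] == "middle").astype(float),
    "category_highest": lambda df: (df["category"] == "highest").astype(float),
    "male": lambda df: df["male"].astype(float),
    "age_above_median": lambda df: df["age_above_median"].astype(float),
    "care_above_median": lambda df: df["care_above_median"].astype(float),
}


def cox_fit(records: pd.DataFrame, terms: Optional[list[str]] = None) -> CoxResult:
    """Cox proportional-hazards fit, mutually adjusted, Efron ties.

    ``records`` is the output of :func:`build_survival_records`; ``terms``
    selects the dummy-coded covariates (all five by default).  Raises
    :class:`ConvergenceError` on monotone likelihood / separation.
    """
    terms = list(_COX_TERMS) if terms is None else terms
    data = pd.DataFrame({"time_days": records["time_days"].astype(float),
                         "event": records["event"].astype(bool)})
    for t in terms:
        data[t] = _COX_TERMS[t](records) if t in _COX_TERMS else records[t].astype(float)
    if data["event"].sum() < 2 or data.loc[data["event"], "time_days"].nunique() < 2:
        raise ConvergenceError("need at least two distinct event times")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="time_days", event_col="event")
    except (_LLConvergenceError, ValueError) as exc:
        raise ConvergenceError(f"Cox fit failed to converge: {exc}") from exc
    summary = cph.summary
    if (summary["coef"].abs() > 20).any() or (summary["se(coef)"] > 100).any():
        bad = summary.index[summary["coef"].abs() > 20].tolist() or summary.index[
            summary["se(coef)"] > 100
        ].tolist()
        raise ConvergenceError(
            f"monotone partial likelihood (covariate separation) for term(s) {bad}"
        )
    table = pd.DataFrame(
        {
            "hazard_ratio": summary["exp(coef)"],
            "ci_lower": summary["exp(coef) lower 95%"],
            "ci_upper": summary["exp(coef) upper 95%"],
            "p_value": summary["p"],
            "log_hr": summary["coef"],
            "se_log_hr": summary["se(coef)"],
        }
    )
    table.index.name = "term"
    return CoxResult(
        table=table,
        n=int(len(data)),
        n_events=int(data["event"].sum()),
        log_likelihood=float(cph.log_likelihood_),
    )
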