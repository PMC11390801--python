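"""Seeded synthetic cohort generator.

The generator emulates a two-facility long-term-care admission cohort:
admissions over a two-year calendar window, observation until discharge,
death, or an administrative cutoff, checklist endorsements at admission,
and three count outcomes.  A single latent severity factor ``z`` (standard
normal) drives both item endorsement (logistic link per item) and the
outcome count rates (log link, negative-binomial counts), which is the
minimal structure producing realistic score-outcome rank correlations.
Mortality follows an exponential hazard multiplied by a planted contrast
per revised-score category, so the proportional-hazards analysis is an
exact parameter-recovery exercise.

Antibiotic administrations are materialized as non-overlapping runs of
3-10 consecutive days separated by at least 3 days, so the episode
segmentation rule reconstructs the planted episode count exactly.

Defaults (``configs/generator_defaults.yaml``) are frozen output of
:mod:`nascher.calibrate` against the published cohort marginals.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit
from scipy.stats import truncnorm

from .cohort import Cohort, observation_days
from .scoring import CategoryBoundaries, ScoreConfig, categorize, compute_score, load_config


@dataclass(frozen=True)
class ItemParams:
    """Endorsement model for one item: P(endorsed | z) = expit(intercept + loading * z)."""

    intercept: float
    loading: float


@dataclass(frozen=True)
class CountParams:
    """Negative-binomial count model for one outcome.

    Expected count = exp(log_baseline + severity * z) * observation_days
    / period_days; ``dispersion`` is the NB shape (smaller = more
    overdispersed), ``period_days`` 365.25 for yearly outcomes, 7 for
    the weekly documentation outcome.
    """

    log_baseline: float
    severity: float
    dispersion: float
    period_days: float


@dataclass(frozen=True)
class HazardParams:
    """Constant competing hazards (per day).

    Death hazard is ``baseline_death_hazard`` multiplied by the planted
    category contrast (1 / theta_middle / theta_highest); discharge is an
    independent exponential censoring process.
    """

    baseline_death_hazard: float
    discharge_hazard: float
    theta_middle: float = 1.80
    theta_highest: float = 3.03
    died_in_hospital_fraction: float = 29 / 204
    discharge_probs: tuple[float, float, float] = (29 / 42, 5 / 42, 8 / 42)


@dataclass(frozen=True)
class GeneratorParams:
    """Every parameter of the synthetic cohort model."""

    n_residents: int = 396
    admission_window: tuple[datetime.date, datetime.date] = (
        datetime.date(2020, 8, 1),
        datetime.date(2022, 7, 31),
    )
    cutoff_date: datetime.date = datetime.date(2023, 5, 31)
    male_fraction: float = 0.434
    age_mean: float = 81.2
    age_sd: float = 10.8
    age_bounds: tuple[float, float] = (40.0, 104.0)
    care_level_probs: tuple[float, ...] = (0.01, 0.02, 0.07, 0.18, 0.32, 0.24, 0.11, 0.05)
    item_params: Mapping[str, ItemParams] = field(default_factory=dict)
    count_params: Mapping[str, CountParams] = field(default_factory=dict)
    hazard_params: HazardParams = HazardParams(
        baseline_death_hazard=2e-3, discharge_hazard=2.5e-4
    )
    category_boundaries: CategoryBoundaries = CategoryBoundaries(low_max=4, high_min=8)
    scoring_config: str = "revised"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if abs(sum(self.care_level_probs) - 1.0) > 1e-9:
            raise ValueError("care_level_probs must sum to 1")
        if self.hazard_params.baseline_death_hazard <= 0 or self.hazard_params.discharge_hazard <= 0:
            raise ValueError("hazards must be positive")
        for name, cp in self.count_params.items():
            if cp.dispersion <= 0:
                raise ValueError(f"dispersion for {name} must be positive")

    @classmethod
    def from_yaml(cls, path) -> "GeneratorParams":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "GeneratorParams":
        hz = raw["hazards"]
        return cls(
            n_residents=int(raw["n_residents"]),
            admission_window=tuple(_as_date(d) for d in raw["admission_window"]),
            cutoff_date=_as_date(raw["cutoff_date"]),
            male_fraction=float(raw["male_fraction"]),
            age_mean=float(raw["age_mean"]),
            age_sd=float(raw["age_sd"]),
            age_bounds=tuple(float(v) for v in raw["age_bounds"]),
            care_level_probs=tuple(float(v) for v in raw["care_level_probs"]),
            item_params={
                name: ItemParams(float(p["intercept"]), float(p["loading"]))
                for name, p in raw["items"].items()
            },
            count_params={
                name: CountParams(
                    float(p["log_baseline"]),
                    float(p["severity"]),
                    float(p["dispersion"]),
                    float(p["period_days"]),
                )
                for name, p in raw["counts"].items()
            },
            hazard_params=HazardParams(
                baseline_death_hazard=float(hz["baseline_death_hazard"]),
                discharge_hazard=float(hz["discharge_hazard"]),
                theta_middle=float(hz.get("theta_middle", 1.80)),
                theta_highest=float(hz.get("theta_highest", 3.03)),
                died_in_hospital_fraction=float(hz.get("died_in_hospital_fraction", 29 / 204)),
                discharge_probs=tuple(hz.get("discharge_probs", (29 / 42, 5 / 42, 8 / 42))),
            ),
            category_boundaries=CategoryBoundaries(
                low_max=int(raw["category_boundaries"]["low_max"]),
                high_min=int(raw["category_boundaries"]["high_min"]),
            ),
            scoring_config=raw.get("scoring_config", "revised"),
            seed=raw.get("seed"),
        )

    def to_dict(self) -> dict:
        hp = self.hazard_params
        return {
            "n_residents": int(self.n_residents),
            "admission_window": [d.isoformat() for d in self.admission_window],
            "cutoff_date": self.cutoff_date.isoformat(),
            "male_fraction": self.male_fraction,
            "age_mean": self.age_mean,
            "age_sd": self.age_sd,
            "age_bounds": list(self.age_bounds),
            "care_level_probs": list(self.care_level_probs),
            "items": {
                name: {"intercept": round(p.intercept, 6), "loading": p.loading}
                for name, p in self.item_params.items()
            },
            "counts": {
                name: {
                    "log_baseline": round(p.log_baseline, 6),
                    "severity": round(p.severity, 6),
                    "dispersion": p.dispersion,
                    "period_days": p.period_days,
                }
                for name, p in self.count_params.items()
            },
            "hazards": {
                "baseline_death_hazard": float(f"{hp.baseline_death_hazard:.6g}"),
                "discharge_hazard": float(f"{hp.discharge_hazard:.6g}"),
                "theta_middle": hp.theta_middle,
                "theta_highest": hp.theta_highest,
                "died_in_hospital_fraction": hp.died_in_hospital_fraction,
                "discharge_probs": list(hp.discharge_probs),
            },
            "category_boundaries": {
                "low_max": self.category_boundaries.low_max,
                "high_min": self.category_boundaries.high_min,
            },
            "scoring_config": self.scoring_config,
            "seed": self.seed,
        }

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path

    def with_seed(self, seed: int) -> "GeneratorParams":
        return replace(self, seed=seed)


def _as_date(value) -> datetime.date:
    if isinstance(value, datetime.date):
        return value
    return datetime.date.fromisoformat(str(value))


def default_params() -> GeneratorParams:
    """The packaged calibrated defaults."""
    ref = resources.files("nascher.configs") / "generator_defaults.yaml"
    with resources.as_file(ref) as path:
        return GeneratorParams.from_yaml(path)


def _place_episodes(rng: np.random.Generator, n_episodes: int, window_days: int):
    """Day offsets (0-based within the window) for antibiotic runs.

    Runs are 3-10 days (truncated by the window), separated by at least
    3 antibiotic-free days; the episode count is reduced when the window
    cannot hold it.  Returns (offsets, placed_episode_count).
    """
    if n_episodes <= 0 or window_days <= 0:
        return np.empty(0, dtype=int), 0
    lengths = rng.integers(3, 11, size=n_episodes)
    lengths = np.minimum(lengths, window_days)
    m = n_episodes
    while m > 1 and lengths[:m].sum() + 3 * (m - 1) > window_days:
        m -= 1
    lengths = lengths[:m]
    total = int(lengths.sum()) + 3 * (m - 1)
    slack = window_days - total
    extra = rng.multinomial(slack, np.full(m + 1, 1.0 / (m + 1)))
    offsets = []
    cursor = int(extra[0])
    for i in range(m):
        offsets.extend(range(cursor, cursor + int(lengths[i])))
        cursor += int(lengths[i]) + 3 + int(extra[i + 1])
    return np.asarray(offsets, dtype=int), m


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    """NB draws via the Poisson-Gamma mixture (supports real dispersion)."""
    lam = rng.gamma(shape=dispersion, scale=np.maximum(mean, 1e-12) / dispersion)
    return rng.poisson(lam)


def generate_cohort_with_truth(
    params: GeneratorParams, seed: Optional[int] = None
) -> tuple[Cohort, pd.DataFrame]:
    """Generate a cohort plus the per-resident latent truth table.

    The truth table carries the latent severity, the planted score
    category, and the planted outcome counts (antibiotic episodes after
    any window-feasibility reduction), for parameter-recovery tests.
    Deterministic given (params, seed); ``seed`` overrides
    ``params.seed``.
    """
    if not params.item_params or not params.count_params:
        raise ValueError("item_params and count_params must be populated (see default_params)")
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    n = params.n_residents
    config = load_config(params.scoring_config)
    missing = set(config.item_names) - set(params.item_params)
    if missing:
        raise ValueError(f"scoring config items without generator parameters: {sorted(missing)}")

    ids = [f"R{i + 1:04d}" for i in range(n)]
    sex = np.where(rng.random(n) < params.male_fraction, "male", "female")
    lo, hi = params.age_bounds
    a, b = (lo - params.age_mean) / params.age_sd, (hi - params.age_mean) / params.age_sd
    age = np.round(
        truncnorm.rvs(a, b, loc=params.age_mean, scale=params.age_sd, size=n, random_state=rng), 1
    )
    care = rng.choice(8, size=n, p=np.asarray(params.care_level_probs))

    w0, w1 = params.admission_window
    window_span = (w1 - w0).days
    admission_offsets = rng.integers(0, window_span + 1, size=n)
    admissions = [w0 + datetime.timedelta(days=int(o)) for o in admission_offsets]

    z = rng.standard_normal(n)

    item_names = list(params.item_params)
    endorsed = {}
    for name in item_names:
        ip = params.item_params[name]
        endorsed[name] = rng.random(n) < expit(ip.intercept + ip.loading * z)

    scores = np.array(
        [
            compute_score(
                {nm for nm in config.item_names if endorsed[nm][i]}, config
            )
            for i in range(n)
        ]
    )
    categories = np.array([categorize(int(s), params.category_boundaries) for s in scores])

    hp = params.hazard_params
    theta = np.where(
        categories == "highest", hp.theta_highest, np.where(categories == "middle", hp.theta_middle, 1.0)
    )
    death_raw = rng.exponential(1.0 / (hp.baseline_death_hazard * theta), size=n)
    discharge_raw = rng.exponential(1.0 / hp.discharge_hazard, size=n)
    death_day = np.maximum(1, np.ceil(death_raw)).astype(int)
    discharge_day = np.maximum(1, np.ceil(discharge_raw)).astype(int)
    admin_days = np.array([(params.cutoff_date - adm).days + 1 for adm in admissions])

    obs_days = np.minimum.reduce([death_day, discharge_day, admin_days])
    died = death_day <= np.minimum(discharge_day, admin_days)
    discharged = ~died & (discharge_day < admin_days)

    death_in_hospital = rng.random(n) < hp.died_in_hospital_fraction
    discharge_reason = rng.choice(
        ["discharged_home", "admitted_to_hospital", "discharged_other_home"],
        size=n,
        p=np.asarray(hp.discharge_probs),
    )
    end_reason = np.where(
        died,
        np.where(death_in_hospital, "died_in_hospital", "died_in_facility"),
        np.where(discharged, discharge_reason, "still_resident"),
    )
    end_dates = [adm + datetime.timedelta(days=int(d) - 1) for adm, d in zip(admissions, obs_days)]

    counts = {}
    for outcome, cp in params.count_params.items():
        mean = np.exp(cp.log_baseline + cp.severity * z) * obs_days / cp.period_days
        counts[outcome] = _negative_binomial(rng, mean, cp.dispersion)

    event_rows: list[tuple[str, str, datetime.date]] = []
    placed_episodes = np.zeros(n, dtype=int)
    for i, rid in enumerate(ids):
        d = int(obs_days[i])
        adm = admissions[i]
        for outcome, event_type in (
            ("med_changes", "medication_change"),
            ("documentations", "doctor_documentation"),
        ):
            k = int(counts[outcome][i])
            if k:
                for off in rng.integers(0, d, size=k):
                    event_rows.append((rid, event_type, adm + datetime.timedelta(days=int(off))))
        offsets, m = _place_episodes(rng, int(counts["antibiotic_episodes"][i]), d)
        placed_episodes[i] = m
        for off in offsets:
            event_rows.append(
                (rid, "antibiotic_administration", adm + datetime.timedelta(days=int(off)))
            )

    residents = pd.DataFrame(
        {
            "resident_id": ids,
            "sex": sex,
            "age_years": age,
            "care_level": care.astype(int),
            "admission_date": pd.to_datetime(admissions),
            "end_date": pd.to_datetime(end_dates),
            "end_reason": end_reason,
        }
    )
    endo_rows = [
        (rid, name, 1)
        for name in item_names
        for i, rid in enumerate(ids)
        if endorsed[name][i]
    ]
    endorsements = pd.DataFrame(endo_rows, columns=["resident_id", "item_name", "endorsed"])
    events = pd.DataFrame(event_rows, columns=["resident_id", "event_type", "event_date"])
    if len(events):
        events["event_date"] = pd.to_datetime(events["event_date"])
    cohort = Cohort(residents=residents, endorsements=endorsements, events=events)
    if n:
        cohort.validate()

    truth = pd.DataFrame(
        {
            "resident_id": ids,
            "z": z,
            "score": scores,
            "category": categories,
            "observation_days": obs_days,
            "died": died,
            "n_med_changes": counts["med_changes"].astype(int),
            "n_documentations": counts["documentations"].astype(int),
            "n_antibiotic_episodes": placed_episodes,
        }
    ).set_index("resident_id")
    return cohort, truth


def generate_cohort(params: GeneratorParams, seed: Optional[int] = None) -> Cohort:
    """Generate a validated synthetic cohort (see
    :func:`generate_cohort_with_truth` for the latent truth)."""
    cohort, _ = generate_cohort_with_truth(params, seed=seed)
    return cohort
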