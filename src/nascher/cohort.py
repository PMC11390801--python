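"""Cohort data model and tabular I/O.

A cohort is three tables: residents (one row per admitted person),
item endorsements at admission (binary checklist items), and dated
clinical events (medication changes, ward-doctor documentations,
antibiotic administrations).  Files are plain UTF-8 CSV with a header
row; dates are ISO-8601 calendar days — the day is the finest time
granularity used anywhere in the package.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CohortValidationError, SchemaError

SEXES = ("male", "female")

#: Reasons observation ends.  Death in the facility and death after
#: transfer to an acute hospital both count as death outcomes; all other
#: reasons censor the survival analysis.
END_REASONS = (
    "still_resident",
    "discharged_home",
    "admitted_to_hospital",
    "discharged_other_home",
    "died_in_facility",
    "died_in_hospital",
)
DEATH_REASONS = frozenset({"died_in_facility", "died_in_hospital"})

EVENT_TYPES = (
    "medication_change",
    "doctor_documentation",
    "antibiotic_administration",
)

#: Administrative end of follow-up used by the study design (configurable
#: per cohort at generation time).
DEFAULT_CUTOFF = datetime.date(2023, 5, 31)

RESIDENT_COLUMNS = [
    "resident_id",
    "sex",
    "age_years",
    "care_level",
    "admission_date",
    "end_date",
    "end_reason",
]
ENDORSEMENT_COLUMNS = ["resident_id", "item_name", "endorsed"]
EVENT_COLUMNS = ["resident_id", "event_type", "event_date"]


@dataclass(frozen=True)
class Resident:
    """One admitted person with an observation window.

    ``care_level`` is the Austrian long-term-care allowance level
    (*Pflegestufe*), an integer 0-7; level >= 3 is the admission
    prerequisite for a nursing hospital but lower levels can occur in
    historical records.
    """

    resident_id: str
    sex: str
    age_years: float
    care_level: int
    admission_date: datetime.date
    end_date: datetime.date
    end_reason: str

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise CohortValidationError(f"unknown sex {self.sex!r}")
        if self.end_reason not in END_REASONS:
            raise CohortValidationError(f"unknown end_reason {self.end_reason!r}")
        if self.age_years < 0:
            raise CohortValidationError("age_years must be non-negative")
        if not 0 <= self.care_level <= 7:
            raise CohortValidationError("care_level must be in [0, 7]")
        if self.end_date < self.admission_date:
            raise CohortValidationError(
                f"resident {self.resident_id}: end_date {self.end_date} precedes "
                f"admission_date {self.admission_date}"
            )

    @property
    def died(self) -> bool:
        return self.end_reason in DEATH_REASONS


def observation_days(resident_or_admission, end_date=None) -> int:
    """Length of the observation window in days, both endpoints counted.

    Accepts either a :class:`Resident` or an (admission_date, end_date)
    pair.  Admission and end on the same calendar day give 1 day, so the
    minimum is 1 for any valid window.
    """
    if end_date is None:
        admission, end = resident_or_admission.admission_date, resident_or_admission.end_date
    else:
        admission, end = resident_or_admission, end_date
    delta = (pd.Timestamp(end) - pd.Timestamp(admission)).days + 1
    if delta < 1:
        raise CohortValidationError("end_date precedes admission_date")
    return int(delta)


def observation_days_series(residents: pd.DataFrame) -> pd.Series:
    """Vectorized observation window lengths, indexed by resident_id."""
    days = (
        pd.to_datetime(residents["end_date"]) - pd.to_datetime(residents["admission_date"])
    ).dt.days + 1
    if (days < 1).any():
        bad = residents.loc[days < 1, "resident_id"].tolist()
        raise CohortValidationError(f"end_date precedes admission_date for {bad}")
    return pd.Series(days.to_numpy(), index=residents["resident_id"].to_numpy(), name="observation_days")


@dataclass
class Cohort:
    """Residents, their admission endorsements, and their dated events.

    The three tables are plain :class:`pandas.DataFrame` objects with the
    documented column schemas; :meth:`validate` enforces every structural
    invariant and is called by :func:`read_cohort` and by the generator.
    """

    residents: pd.DataFrame
    endorsements: pd.DataFrame
    events: pd.DataFrame

    @property
    def n_residents(self) -> int:
        return len(self.residents)

    def resident(self, resident_id) -> Resident:
        row = self.residents.loc[self.residents["resident_id"] == resident_id]
        if row.empty:
            raise KeyError(resident_id)
        r = row.iloc[0]
        return Resident(
            resident_id=r["resident_id"],
            sex=r["sex"],
            age_years=float(r["age_years"]),
            care_level=int(r["care_level"]),
            admission_date=pd.Timestamp(r["admission_date"]).date(),
            end_date=pd.Timestamp(r["end_date"]).date(),
            end_reason=r["end_reason"],
        )

    def endorsed_items(self, resident_id) -> set[str]:
        mask = (self.endorsements["resident_id"] == resident_id) & (
            self.endorsements["endorsed"].astype(int) == 1
        )
        return set(self.endorsements.loc[mask, "item_name"])

    def observation_days(self) -> pd.Series:
        return observation_days_series(self.residents)

    def validate(self) -> "Cohort":
        _require_columns(self.residents, RESIDENT_COLUMNS, "residents")
        _require_columns(self.endorsements, ENDORSEMENT_COLUMNS, "endorsements")
        _require_columns(self.events, EVENT_COLUMNS, "events")

        res = self.residents
        if res["resident_id"].duplicated().any():
            dup = res.loc[res["resident_id"].duplicated(), "resident_id"].tolist()
            raise CohortValidationError(f"duplicate resident_id values: {dup}")
        bad_sex = set(res["sex"]) - set(SEXES)
        if bad_sex:
            raise CohortValidationError(f"unknown sex values: {sorted(bad_sex)}")
        bad_reason = set(res["end_reason"]) - set(END_REASONS)
        if bad_reason:
            raise CohortValidationError(f"unknown end_reason values: {sorted(bad_reason)}")
        if (res["age_years"].astype(float) < 0).any():
            raise CohortValidationError("negative age_years")
        care = res["care_level"].astype(int)
        if ((care < 0) | (care > 7)).any():
            raise CohortValidationError("care_level outside [0, 7]")
        observation_days_series(res)  # raises on inverted windows

        known = set(res["resident_id"])
        for name, table, id_col in (
            ("endorsements", self.endorsements, "resident_id"),
            ("events", self.events, "resident_id"),
        ):
            orphans = set(table[id_col]) - known
            if orphans:
                raise CohortValidationError(
                    f"{name} reference unknown resident_id values: {sorted(orphans)[:5]}"
                )

        if self.endorsements.duplicated(["resident_id", "item_name"]).any():
            dup = self.endorsements.loc[
                self.endorsements.duplicated(["resident_id", "item_name"]),
                ["resident_id", "item_name"],
            ]
            raise CohortValidationError(
                f"duplicate (resident_id, item_name) endorsements: {dup.values[:5].tolist()}"
            )
        endorsed = self.endorsements["endorsed"].astype(int)
        if (~endorsed.isin([0, 1])).any():
            raise CohortValidationError("endorsed must be 0/1")

        bad_type = set(self.events["event_type"]) - set(EVENT_TYPES)
        if bad_type:
            raise CohortValidationError(f"unknown event_type values: {sorted(bad_type)}")
        if len(self.events):
            ev = self.events.merge(
                res[["resident_id", "admission_date", "end_date"]], on="resident_id"
            )
            event_date = pd.to_datetime(ev["event_date"])
            out = (event_date < pd.to_datetime(ev["admission_date"])) | (
                event_date > pd.to_datetime(ev["end_date"])
            )
            if out.any():
                bad = ev.loc[out, ["resident_id", "event_date"]].values[:5].tolist()
                raise CohortValidationError(
                    f"events outside the resident observation window: {bad}"
                )
        return self

    def __eq__(self, other) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return all(
            _canonical(a).equals(_canonical(b))
            for a, b in (
                (self.residents, other.residents),
                (self.endorsements, other.endorsements),
                (self.events, other.events),
            )
        )


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if col.endswith("_date"):
            out[col] = pd.to_datetime(out[col])
        elif col in ("endorsed", "care_level"):
            out[col] = out[col].astype(int)
        elif col == "age_years":
            out[col] = out[col].astype(float)
        else:
            out[col] = out[col].astype(str)
    return out.sort_values(list(out.columns)).reset_index(drop=True)


def _require_columns(df: pd.DataFrame, columns, name: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{name} table is missing required column(s): {missing}")


def _parse_dates(df: pd.DataFrame, column: str, table: str) -> pd.DataFrame:
    parsed = pd.to_datetime(df[column], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df[column].notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise SchemaError(
            f"{table} row {row}: cannot parse {column}={df[column].iloc[row]!r} as YYYY-MM-DD"
        )
    if df[column].isna().any():
        row = int(np.flatnonzero(df[column].isna().to_numpy())[0])
        raise SchemaError(f"{table} row {row}: missing {column}")
    out = df.copy()
    out[column] = parsed
    return out


def _paths(directory_or_paths) -> tuple[Path, Path, Path]:
    if isinstance(directory_or_paths, (str, Path)):
        d = Path(directory_or_paths)
        return d / "residents.csv", d / "endorsements.csv", d / "events.csv"
    residents, endorsements, events = directory_or_paths
    return Path(residents), Path(endorsements), Path(events)


def read_cohort(directory_or_paths) -> Cohort:
    """Read and validate a cohort from ``residents.csv``,
    ``endorsements.csv`` and ``events.csv``.

    Accepts a directory containing the three files or an explicit
    (residents, endorsements, events) path triple.  Raises
    :class:`SchemaError` for missing columns or malformed dates and
    :class:`CohortValidationError` for referential or range violations.
    """
    rpath, npath, epath = _paths(directory_or_paths)
    residents = pd.read_csv(rpath, dtype={"resident_id": str})
    endorsements = pd.read_csv(npath, dtype={"resident_id": str, "item_name": str})
    events = pd.read_csv(epath, dtype={"resident_id": str})
    _require_columns(residents, RESIDENT_COLUMNS, "residents")
    _require_columns(endorsements, ENDORSEMENT_COLUMNS, "endorsements")
    _require_columns(events, EVENT_COLUMNS, "events")
    residents = _parse_dates(residents, "admission_date", "residents")
    residents = _parse_dates(residents, "end_date", "residents")
    events = _parse_dates(events, "event_date", "events")
    return Cohort(residents=residents, endorsements=endorsements, events=events).validate()


def write_cohort(cohort: Cohort, directory) -> tuple[Path, Path, Path]:
    """Write the three cohort tables as UTF-8 CSV; returns the paths.

    Dates are serialized as ISO-8601 days so that
    ``read_cohort(write_cohort(c))`` reproduces ``c`` field-for-field.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = (d / "residents.csv", d / "endorsements.csv", d / "events.csv")

    residents = cohort.residents.copy()
    for col in ("admission_date", "end_date"):
        residents[col] = pd.to_datetime(residents[col]).dt.strftime("%Y-%m-%d")
    events = cohort.events.copy()
    if len(events):
        events["event_date"] = pd.to_datetime(events["event_date"]).dt.strftime("%Y-%m-%d")

    residents[RESIDENT_COLUMNS].to_csv(paths[0], index=False)
    cohort.endorsements[ENDORSEMENT_COLUMNS].to_csv(paths[1], index=False)
    events[EVENT_COLUMNS].to_csv(paths[2], index=False)
    return paths
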