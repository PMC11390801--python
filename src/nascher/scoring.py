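"""Additive checklist score configurations, scoring, and quartile
stratification.

The medical-needs checklist is additive: every endorsed item contributes
its point value, an optional cap truncates the total.  Two
configurations ship with the package: the ``original`` 26-item scoring
(all items one point, total capped at 20) and the ``revised`` 12-item
scoring (five 2-point items, seven 1-point items, maximum 17, no cap).
Only nine of the original items are publicly named; the remainder are
documented placeholders a site can replace with its own item list.

Scores are stratified into three categories — lowest quartile, merged
middle quartiles, highest quartile.  The packaged default boundaries are
the published values (original: <=14 / 15-19 / >=20; revised: <=4 / 5-7
/ >=8); :func:`derive_category_boundaries` recomputes boundaries from a
score sample with a nearest-rank quartile rule and may differ from the
published ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort
from .errors import DegenerateDistributionError, UnknownItemError

DOMAINS = (
    "geriatric_patient",
    "medical_incident_risk",
    "special_measures",
    "advanced_chronic_disease",
)

CATEGORIES = ("lowest", "middle", "highest")


@dataclass(frozen=True)
class ScoreItem:
    """A single checklist item worth ``points`` when endorsed."""

    item_name: str
    points: int = 1
    domain_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.points < 1:
            raise ValueError(f"item {self.item_name!r}: points must be >= 1")
        if self.domain_label is not None and self.domain_label not in DOMAINS:
            raise ValueError(f"item {self.item_name!r}: unknown domain {self.domain_label!r}")


@dataclass(frozen=True)
class ScoreConfig:
    """A named additive checklist: items, per-item points, optional cap."""

    config_name: str
    items: tuple[ScoreItem, ...]
    score_cap: Optional[int] = None

    def __post_init__(self) -> None:
        names = [it.item_name for it in self.items]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate item names in config {self.config_name!r}: {dup}")
        if self.score_cap is not None and self.score_cap < 1:
            raise ValueError("score_cap must be a positive integer")

    @property
    def item_names(self) -> tuple[str, ...]:
        return tuple(it.item_name for it in self.items)

    @property
    def points(self) -> Mapping[str, int]:
        return {it.item_name: it.points for it in self.items}

    @property
    def max_achievable(self) -> int:
        total = sum(it.points for it in self.items)
        return min(total, self.score_cap) if self.score_cap is not None else total

    @classmethod
    def from_yaml(cls, path) -> "ScoreConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ScoreConfig":
        items = tuple(
            ScoreItem(
                item_name=entry["name"],
                points=int(entry.get("points", 1)),
                domain_label=entry.get("domain"),
            )
            for entry in raw["items"]
        )
        return cls(config_name=raw["name"], items=items, score_cap=raw.get("cap"))

    def to_dict(self) -> dict:
        out: dict = {"name": self.config_name}
        if self.score_cap is not None:
            out["cap"] = int(self.score_cap)
        out["items"] = [
            {"name": it.item_name, "points": int(it.points), "domain": it.domain_label}
            for it in self.items
        ]
        return out

    def to_yaml(self, path) -> Path:
        path = Path(path)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
        return path


def load_config(name_or_path) -> ScoreConfig:
    """Load a packaged config (``"original"`` / ``"revised"``) or a YAML file."""
    if name_or_path in ("original", "revised"):
        ref = resources.files("nascher.configs") / f"nascher_{name_or_path}.yaml"
        with resources.as_file(ref) as path:
            return ScoreConfig.from_yaml(path)
    return ScoreConfig.from_yaml(name_or_path)


def compute_score(endorsed_items: Iterable[str], config: ScoreConfig) -> int:
    """Additive score of an endorsement set under ``config``.

    Unknown item names are rejected rather than ignored: silently
    dropping a typo would deflate a resident's score.
    """
    endorsed = set(endorsed_items)
    points = config.points
    unknown = endorsed - points.keys()
    if unknown:
        raise UnknownItemError(
            f"item(s) {sorted(unknown)} not in config {config.config_name!r}"
        )
    total = sum(points[name] for name in endorsed)
    if config.score_cap is not None:
        total = min(total, config.score_cap)
    return total


def score_cohort(cohort: Cohort, config: ScoreConfig, strict: bool = True) -> pd.Series:
    """One score per resident (admission endorsement set); residents with
    no endorsement rows score 0.  Returns a Series indexed by resident_id.

    With ``strict`` (default) endorsement item names outside the config
    are rejected.  ``strict=False`` ignores them instead — the intended
    mode when scoring a sub-checklist (e.g. the revised 12-item scoring)
    against a cohort assessed with the full instrument.
    """
    points = config.points
    endo = cohort.endorsements
    unknown = set(endo["item_name"]) - points.keys()
    if unknown and strict:
        raise UnknownItemError(
            f"endorsement item(s) {sorted(unknown)} not in config {config.config_name!r}"
        )
    if unknown:
        endo = endo[endo["item_name"].isin(points)]
    endorsed = endo[endo["endorsed"].astype(int) == 1]
    raw = (
        endorsed.assign(points=endorsed["item_name"].map(points))
        .groupby("resident_id")["points"]
        .sum()
    )
    scores = raw.reindex(cohort.residents["resident_id"], fill_value=0).astype(int)
    if config.score_cap is not None:
        scores = scores.clip(upper=config.score_cap)
    scores.name = f"score_{config.config_name}"
    return scores


@dataclass(frozen=True)
class CategoryBoundaries:
    """Three-way stratification: lowest iff score <= low_max, highest iff
    score >= high_min, middle otherwise."""

    low_max: int
    high_min: int

    def __post_init__(self) -> None:
        if self.low_max >= self.high_min:
            raise ValueError("low_max must be strictly below high_min")


#: Published category boundaries for the packaged configurations.
PAPER_BOUNDARIES: Mapping[str, CategoryBoundaries] = {
    "original": CategoryBoundaries(low_max=14, high_min=20),
    "revised": CategoryBoundaries(low_max=4, high_min=8),
}


def nearest_rank_quantile(values, p: float) -> float:
    """Smallest value whose cumulative proportion is >= p (nearest rank)."""
    arr = np.sort(np.asarray(values))
    if arr.size == 0:
        raise ValueError("empty sample")
    idx = int(np.ceil(p * arr.size)) - 1
    return arr[max(idx, 0)]


def derive_category_boundaries(scores) -> CategoryBoundaries:
    """Quartile-based boundaries: lowest quartile / merged middle
    quartiles / highest quartile, via nearest-rank Q1 and Q3.

    With a discrete score the naive (Q1, Q3) boundaries can leave the
    middle category empty; in that case ``high_min`` is bumped to Q3+1,
    and if Q1 = Q3 the lowest boundary drops to Q1-1 as well.  Raises
    :class:`DegenerateDistributionError` when no adjustment yields three
    non-empty categories (e.g. all scores identical).
    """
    arr = np.asarray(list(scores), dtype=int)
    if arr.size < 4:
        raise DegenerateDistributionError("need at least 4 scores to stratify")
    if np.all(arr == arr[0]):
        raise DegenerateDistributionError("all scores identical; no stratification possible")
    q1 = int(nearest_rank_quantile(arr, 0.25))
    q3 = int(nearest_rank_quantile(arr, 0.75))
    low_max, high_min = q1, q3
    if q1 == q3:
        low_max, high_min = q1 - 1, q3 + 1
    elif not np.any((arr > low_max) & (arr < high_min)):
        high_min = q3 + 1
    boundaries = CategoryBoundaries(low_max=low_max, high_min=high_min)
    counts = categorize_series(pd.Series(arr), boundaries).value_counts()
    if any(counts.get(cat, 0) == 0 for cat in CATEGORIES):
        raise DegenerateDistributionError(
            f"boundaries {boundaries} leave an empty category (counts: {counts.to_dict()})"
        )
    return boundaries


def categorize(score: int, boundaries: CategoryBoundaries) -> str:
    """Map a score to ``lowest`` / ``middle`` / ``highest``."""
    if score <= boundaries.low_max:
        return "lowest"
    if score >= boundaries.high_min:
        return "highest"
    return "middle"


def categorize_series(scores: pd.Series, boundaries: CategoryBoundaries) -> pd.Series:
    """Vectorized :func:`categorize`; preserves the index."""
    out = pd.Series("middle", index=scores.index, name="category", dtype=object)
    out[scores <= boundaries.low_max] = "lowest"
    out[scores >= boundaries.high_min] = "highest"
    return out
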