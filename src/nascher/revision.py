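"""Data-driven revision of the additive checklist.

The revision derives an alternative scoring from cohort data in three
ordered steps:

1. **prevalence pruning** — items endorsed by fewer than 5% of
   residents are removed;
2. **direction pruning** — items whose endorsement is inversely
   associated with the medical-needs outcomes are removed;
3. **two-tier weighting** — items significantly positively associated
   with the outcomes receive 2 points, the remainder 1 point.

The association measure is the Spearman rank correlation between the
binary endorsement indicator and each of the three window-normalized
outcome rates.  "Associated with the outcomes" is operationalized as a
configurable majority rule: significant (two-sided p < alpha) positive
correlation with at least ``min_outcomes`` of the three outcomes.  No
multiple-testing correction is applied, and the revision is derived and
evaluated on the same cohort — both deliberate reproductions of the
source procedure, not recommendations.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

from .cohort import Cohort
from .errors import NascherError
from .outcomes import OUTCOME_RATE_COLUMNS, compute_outcome_rates
from .scoring import ScoreConfig, ScoreItem
from .stats import spearman


@dataclass(frozen=True)
class RevisionThresholds:
    """Tunable knobs of the revision procedure (defaults reproduce the
    published rule set)."""

    min_prevalence: float = 0.05  # strict: prevalence < 5% removes the item
    alpha: float = 0.05  # two-sided significance level per outcome
    min_outcomes: int = 2  # "the outcomes" = at least this many of the 3


@dataclass(frozen=True)
class ItemAssociation:
    """Prevalence and per-outcome (rho, p) pairs for one item.

    Zero-variance items (endorsed by all residents or none) have
    undefined correlations, recorded as NaN and treated as "lesser
    association" downstream.
    """

    item_name: str
    prevalence: float
    per_outcome: Mapping[str, tuple[float, float]]

    def n_significant_positive(self, alpha: float) -> int:
        return sum(
            1
            for rho, p in self.per_outcome.values()
            if not math.isnan(rho) and rho > 0 and p < alpha
        )

    def n_negative(self) -> int:
        return sum(1 for rho, _ in self.per_outcome.values() if not math.isnan(rho) and rho < 0)


def item_prevalence(cohort: Cohort, config: ScoreConfig) -> pd.Series:
    """Proportion of residents endorsing each config item.

    Residents without a row for an item count as not endorsed, so the
    denominator is always the full cohort size.
    """
    if cohort.n_residents == 0:
        raise NascherError("empty cohort: prevalence undefined")
    endo = cohort.endorsements
    endorsed = endo[endo["endorsed"].astype(int) == 1]
    counts = endorsed.groupby("item_name").size()
    prev = counts.reindex(config.item_names, fill_value=0) / cohort.n_residents
    prev.name = "prevalence"
    return prev


def item_outcome_associations(
    cohort: Cohort,
    config: ScoreConfig,
    outcome_rates: Optional[pd.DataFrame] = None,
) -> list[ItemAssociation]:
    """Rank correlation of each item's endorsement indicator with each
    outcome rate, with two-sided p-values."""
    if outcome_rates is None:
        outcome_rates = compute_outcome_rates(cohort)
    ids = cohort.residents["resident_id"]
    rates = outcome_rates.reindex(ids)
    if rates[list(OUTCOME_RATE_COLUMNS)].isna().any().any():
        raise NascherError("outcome rates missing for some residents")
    endo = cohort.endorsements
    endorsed = endo[endo["endorsed"].astype(int) == 1]
    prev = item_prevalence(cohort, config)

    out = []
    for item in config.item_names:
        holders = set(endorsed.loc[endorsed["item_name"] == item, "resident_id"])
        indicator = ids.isin(holders).astype(float).to_numpy()
        per_outcome = {}
        for col in OUTCOME_RATE_COLUMNS:
            y = rates[col].to_numpy()
            if indicator.min() == indicator.max() or y.min() == y.max():
                per_outcome[col] = (math.nan, math.nan)
            else:
                res = spearman(indicator, y)
                per_outcome[col] = (res["rho"], res["p_value"])
        out.append(
            ItemAssociation(item_name=item, prevalence=float(prev[item]), per_outcome=per_outcome)
        )
    return out


@dataclass
class RevisionReport:
    """Outcome of one revision run: which items were removed and why,
    the two weight tiers, and the resulting configuration."""

    removed_rare: list[str]
    removed_inverse: list[str]
    two_point_items: list[str]
    one_point_items: list[str]
    config: ScoreConfig
    associations: list[ItemAssociation] = field(default_factory=list)
    thresholds: RevisionThresholds = field(default_factory=RevisionThresholds)

    def to_dict(self) -> dict:
        return {
            "removed_rare": self.removed_rare,
            "removed_inverse": self.removed_inverse,
            "two_point_items": self.two_point_items,
            "one_point_items": self.one_point_items,
            "thresholds": {
                "min_prevalence": self.thresholds.min_prevalence,
                "alpha": self.thresholds.alpha,
                "min_outcomes": self.thresholds.min_outcomes,
            },
            "config": self.config.to_dict(),
            "associations": [
                {
                    "item_name": a.item_name,
                    "prevalence": a.prevalence,
                    "per_outcome": {
                        k: {"rho": rho, "p_value": p} for k, (rho, p) in a.per_outcome.items()
                    },
                }
                for a in self.associations
            ],
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, allow_nan=True), encoding="utf-8")
        return path


def derive_revised_config(
    cohort: Cohort,
    base_config: ScoreConfig,
    thresholds: RevisionThresholds = RevisionThresholds(),
    outcome_rates: Optional[pd.DataFrame] = None,
    config_name: str = "revised_derived",
) -> RevisionReport:
    """Run the three-step revision on a cohort.

    Deterministic given the cohort and thresholds.  Raises
    :class:`NascherError` if every item is pruned.
    """
    prev = item_prevalence(cohort, base_config)
    removed_rare = [name for name in base_config.item_names if prev[name] < thresholds.min_prevalence]
    survivors = [name for name in base_config.item_names if name not in removed_rare]
    if not survivors:
        raise NascherError("revision removed every item (all below prevalence threshold)")

    surviving_config = ScoreConfig(
        config_name="_survivors",
        items=tuple(it for it in base_config.items if it.item_name in survivors),
    )
    associations = item_outcome_associations(cohort, surviving_config, outcome_rates)
    by_name = {a.item_name: a for a in associations}

    removed_inverse = [
        name for name in survivors if by_name[name].n_negative() >= thresholds.min_outcomes
    ]
    kept = [name for name in survivors if name not in removed_inverse]
    if not kept:
        raise NascherError("revision removed every item (inverse associations)")

    two_point = [
        name
        for name in kept
        if by_name[name].n_significant_positive(thresholds.alpha) >= thresholds.min_outcomes
    ]
    one_point = [name for name in kept if name not in two_point]

    domains = {it.item_name: it.domain_label for it in base_config.items}
    items = tuple(
        ScoreItem(item_name=name, points=2 if name in two_point else 1, domain_label=domains[name])
        for name in kept
    )
    config = ScoreConfig(config_name=config_name, items=items, score_cap=None)
    return RevisionReport(
        removed_rare=removed_rare,
        removed_inverse=removed_inverse,
        two_point_items=two_point,
        one_point_items=one_point,
        config=config,
        associations=associations,
        thresholds=thresholds,
    )
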