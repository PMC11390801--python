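"""End-to-end study object: checklist scoring of a cohort, quartile
stratification, outcome correlations, and mortality analysis.

:class:`NascherStudy` is the model object — a cohort plus score
configurations and analysis options; :meth:`NascherStudy.fit` runs the
full battery and returns a :class:`StudyResults` carrying descriptives,
medians by score category with k-sample test p-values, Spearman
correlations, Kaplan-Meier summaries per category, and mutually adjusted
Cox hazard ratios, with a ``summary()`` rendering and JSON export.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import DEATH_REASONS, Cohort, read_cohort
from .errors import ConvergenceError, DegenerateDistributionError
from .outcomes import OUTCOME_RATE_COLUMNS, compute_outcome_rates, summarize_distribution
from .revision import RevisionReport, RevisionThresholds, derive_revised_config
from .scoring import (
    PAPER_BOUNDARIES,
    CategoryBoundaries,
    ScoreConfig,
    categorize_series,
    derive_category_boundaries,
    load_config,
    score_cohort,
)
from .stats import build_survival_records, chi_square_test, cox_fit, km_estimate, kruskal_wallis, spearman

CATEGORY_ORDER = ("lowest", "middle", "highest")


def _clean(value):
    """JSON-safe scalar: NaN/inf -> None, numpy -> python."""
    if value is None:
        return None
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating, float)):
        v = float(value)
        return None if not math.isfinite(v) else v
    return value


@dataclass
class ConfigAnalysis:
    """Analysis battery for one score configuration."""

    config: ScoreConfig
    boundaries: CategoryBoundaries
    boundaries_source: str
    scores: pd.Series
    categories: pd.Series
    score_summary: dict
    spearman: dict  # outcome -> {rho, p_value}
    medians_by_category: pd.DataFrame
    kruskal_p: dict  # outcome -> p
    deaths_by_category: pd.DataFrame
    death_chi2: Optional[dict]
    km: dict  # category -> KMResult
    cox: object  # CoxResult or {"error": ...}

    def to_dict(self) -> dict:
        km = {
            cat: {
                "n": r.n,
                "n_events": r.n_events,
                "median_days": _clean(r.median_days),
                "median_ci": [_clean(r.median_ci[0]), _clean(r.median_ci[1])],
            }
            for cat, r in self.km.items()
        }
        if isinstance(self.cox, dict):
            cox = self.cox
        else:
            cox = {
                "n": self.cox.n,
                "n_events": self.cox.n_events,
                "terms": {
                    term: {k: _clean(v) for k, v in row.items()}
                    for term, row in self.cox.table.to_dict("index").items()
                },
            }
        return {
            "config_name": self.config.config_name,
            "boundaries": {
                "low_max": self.boundaries.low_max,
                "high_min": self.boundaries.high_min,
                "source": self.boundaries_source,
            },
            "score_summary": {k: _clean(v) for k, v in self.score_summary.items()},
            "spearman": {k: {kk: _clean(vv) for kk, vv in v.items()} for k, v in self.spearman.items()},
            "medians_by_category": {
                cat: {k: _clean(v) for k, v in row.items()}
                for cat, row in self.medians_by_category.to_dict("index").items()
            },
            "kruskal_p": {k: _clean(v) for k, v in self.kruskal_p.items()},
            "deaths_by_category": {
                cat: {k: _clean(v) for k, v in row.items()}
                for cat, row in self.deaths_by_category.to_dict("index").items()
            },
            "death_chi2": None
            if self.death_chi2 is None
            else {k: _clean(v) for k, v in self.death_chi2.items()},
            "km": km,
            "cox": cox,
        }


class NascherStudy:
    """The study model: a cohort plus scoring configurations.

    Parameters
    ----------
    cohort
        A validated :class:`~nascher.cohort.Cohort`.
    original_config, revised_config
        Packaged names (``"original"`` / ``"revised"``), YAML paths, or
        :class:`ScoreConfig` objects.  ``revised_config="derive"`` runs
        the data-driven revision on this cohort instead of loading a
        fixed revised configuration.
    boundaries
        ``"paper"`` (published category boundaries where available, with
        a nearest-rank fallback) or ``"derived"`` (always nearest-rank
        quartiles of the observed scores).
    """

    def __init__(
        self,
        cohort: Cohort,
        original_config="original",
        revised_config="revised",
        boundaries: str = "paper",
        revision_thresholds: RevisionThresholds = RevisionThresholds(),
    ) -> None:
        if boundaries not in ("paper", "derived"):
            raise ValueError("boundaries must be 'paper' or 'derived'")
        self.cohort = cohort
        self.original_config = self._resolve(original_config)
        self.revised_config = revised_config if revised_config == "derive" else self._resolve(revised_config)
        self.boundaries = boundaries
        self.revision_thresholds = revision_thresholds

    @staticmethod
    def _resolve(config) -> ScoreConfig:
        return config if isinstance(config, ScoreConfig) else load_config(config)

    @classmethod
    def from_directory(cls, cohort_dir, **kwargs) -> "NascherStudy":
        return cls(read_cohort(cohort_dir), **kwargs)

    # ------------------------------------------------------------------
    def fit(self) -> "StudyResults":
        cohort = self.cohort
        rates = compute_outcome_rates(cohort)
        descriptives = self._descriptives(cohort, rates)

        revision_report: Optional[RevisionReport] = None
        revised = self.revised_config
        if revised == "derive":
            revision_report = derive_revised_config(
                cohort, self.original_config, self.revision_thresholds, outcome_rates=rates
            )
            revised = revision_report.config

        analyses = {}
        for config in (self.original_config, revised):
            analyses[config.config_name] = self._analyze_config(cohort, config, rates)

        provenance = {
            "package_version": __version__,
            "n_residents": cohort.n_residents,
            "n_endorsements": len(cohort.endorsements),
            "n_events": len(cohort.events),
            "boundaries_mode": self.boundaries,
            "config_hashes": {
                cfg.config_name: hashlib.sha256(
                    json.dumps(cfg.to_dict(), sort_keys=True).encode()
                ).hexdigest()[:16]
                for cfg in (self.original_config, revised)
            },
        }
        return StudyResults(
            descriptives=descriptives,
            outcome_rates=rates,
            analyses=analyses,
            revision_report=revision_report,
            provenance=provenance,
        )

    def _analyze_config(self, cohort: Cohort, config: ScoreConfig, rates: pd.DataFrame) -> ConfigAnalysis:
        scores = score_cohort(cohort, config, strict=False)
        source = self.boundaries
        bnd = PAPER_BOUNDARIES.get(config.config_name) if self.boundaries == "paper" else None
        if bnd is None:
            bnd = derive_category_boundaries(scores)
            source = "derived"
        categories = categorize_series(scores, bnd)
        aligned = rates.reindex(scores.index)

        spear = {}
        for col in OUTCOME_RATE_COLUMNS:
            try:
                spear[col] = spearman(scores.to_numpy(), aligned[col].to_numpy())
            except ValueError:
                spear[col] = {"rho": math.nan, "p_value": math.nan}

        med_rows, kw_p = {}, {}
        for col in OUTCOME_RATE_COLUMNS:
            groups = {
                cat: aligned.loc[(categories == cat).to_numpy(), col].to_numpy()
                for cat in CATEGORY_ORDER
            }
            med_rows[col] = {cat: (np.median(g) if g.size else math.nan) for cat, g in groups.items()}
            nonempty = [g for g in groups.values() if g.size]
            try:
                kw_p[col] = kruskal_wallis(*nonempty)["p_value"] if len(nonempty) >= 2 else math.nan
            except ValueError:
                kw_p[col] = math.nan
        medians = pd.DataFrame(med_rows).reindex(CATEGORY_ORDER)

        died = cohort.residents.set_index("resident_id")["end_reason"].isin(DEATH_REASONS)
        died = died.reindex(scores.index)
        deaths = pd.DataFrame(
            {
                "n": categories.value_counts().reindex(CATEGORY_ORDER, fill_value=0),
                "n_deaths": died.groupby(categories).sum().reindex(CATEGORY_ORDER, fill_value=0),
            }
        )
        deaths["death_fraction"] = deaths["n_deaths"] / deaths["n"].replace(0, np.nan)
        table = deaths.loc[deaths["n"] > 0, ["n_deaths"]].assign(
            survived=lambda d: deaths.loc[d.index, "n"] - d["n_deaths"]
        )
        chi2 = None
        if len(table) >= 2 and (table.to_numpy().sum(axis=0) > 0).all():
            try:
                chi2 = chi_square_test(table.to_numpy())
            except ValueError:
                chi2 = None

        records = build_survival_records(cohort, scores, bnd)
        km = {
            cat: km_estimate(
                records.loc[records["category"] == cat, "time_days"],
                records.loc[records["category"] == cat, "event"],
            )
            for cat in CATEGORY_ORDER
            if (records["category"] == cat).any()
        }
        try:
            cox = cox_fit(records)
        except ConvergenceError as exc:
            cox = {"error": f"insufficient events: {exc}"}

        return ConfigAnalysis(
            config=config,
            boundaries=bnd,
            boundaries_source=source,
            scores=scores,
            categories=categories,
            score_summary=summarize_distribution(scores),
            spearman=spear,
            medians_by_category=medians,
            kruskal_p=kw_p,
            deaths_by_category=deaths,
            death_chi2=chi2,
            km=km,
            cox=cox,
        )

    @staticmethod
    def _descriptives(cohort: Cohort, rates: pd.DataFrame) -> dict:
        res = cohort.residents
        return {
            "n_residents": cohort.n_residents,
            "sex_counts": res["sex"].value_counts().to_dict(),
            "age": summarize_distribution(res["age_years"].astype(float)),
            "care_level": summarize_distribution(res["care_level"].astype(float)),
            "observation_days": summarize_distribution(rates["observation_days"]),
            "end_reason_counts": res["end_reason"].value_counts().to_dict(),
            "death_fraction": float(res["end_reason"].isin(DEATH_REASONS).mean()),
            "outcomes": {col: summarize_distribution(rates[col]) for col in OUTCOME_RATE_COLUMNS},
        }


@dataclass
class StudyResults:
    """Fitted study: every table of the analysis battery.

    ``analyses`` maps configuration name to its :class:`ConfigAnalysis`;
    everything is serializable via :meth:`to_dict` and re-computable from
    the input files plus the provenance block.
    """

    descriptives: dict
    outcome_rates: pd.DataFrame
    analyses: dict
    revision_report: Optional[RevisionReport]
    provenance: dict

    def to_dict(self) -> dict:
        desc = json.loads(json.dumps(self.descriptives, default=_clean))
        return {
            "descriptives": desc,
            "configs": {name: a.to_dict() for name, a in self.analyses.items()},
            "revision": None if self.revision_report is None else self.revision_report.to_dict(),
            "provenance": self.provenance,
        }

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, default=_clean), encoding="utf-8")
        return path

    def summary(self) -> str:
        lines = []
        d = self.descriptives
        lines.append(f"Cohort: {d['n_residents']} residents; "
                     f"deaths {d['death_fraction'] * 100:.1f}%")
        lines.append(
            "Observation days: median "
            f"{d['observation_days']['median']:.0f} (range {d['observation_days']['min']:.0f}-"
            f"{d['observation_days']['max']:.0f})"
        )
        for name, a in self.analyses.items():
            lines.append("")
            lines.append(f"[{name}] boundaries <= {a.boundaries.low_max} / >= {a.boundaries.high_min} "
                         f"({a.boundaries_source})")
            lines.append(
                "  score mean {mean:.1f} (SD {sd:.1f}), median {median:.0f}, "
                "skewness {skewness:.2f}".format(**{k: a.score_summary[k] for k in
                                                   ("mean", "sd", "median", "skewness")})
            )
            for col in OUTCOME_RATE_COLUMNS:
                s = a.spearman[col]
                lines.append(f"  Spearman {col}: rho={s['rho']:.2f} (p={s['p_value']:.3g})")
            for cat in CATEGORY_ORDER:
                row = a.deaths_by_category.loc[cat]
                km = a.km.get(cat)
                med = "beyond observation" if km is None or km.median_days is None else f"{km.median_days:.0f} d"
                lines.append(
                    f"  {cat}: n={int(row['n'])}, deaths={int(row['n_deaths'])} "
                    f"({100 * row['death_fraction']:.1f}%), median survival {med}"
                )
            if isinstance(a.cox, dict):
                lines.append(f"  Cox: {a.cox['error']}")
            else:
                for term in ("category_middle", "category_highest"):
                    if term in a.cox.table.index:
                        r = a.cox.table.loc[term]
                        lines.append(
                            f"  Cox HR {term}: {r['hazard_ratio']:.2f} "
                            f"(95% CI {r['ci_lower']:.2f}-{r['ci_upper']:.2f})"
                        )
        if self.revision_report is not None:
            rep = self.revision_report
            lines.append("")
            lines.append(
                f"Revision: removed {len(rep.removed_rare)} rare + {len(rep.removed_inverse)} inverse; "
                f"2-point items: {', '.join(rep.two_point_items)}"
            )
        return "\n".join(lines)

    def plot_km(self, directory) -> list[Path]:
        """Write one Kaplan-Meier step plot per configuration."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for name, a in self.analyses.items():
            fig, ax = plt.subplots(figsize=(6, 4))
            for cat in CATEGORY_ORDER:
                if cat in a.km:
                    sf = a.km[cat].survival_function
                    ax.step(sf.index, sf["survival"], where="post", label=cat)
            ax.set_xlabel("days since admission")
            ax.set_ylabel("survival probability")
            ax.set_ylim(0, 1.02)
            ax.legend(title="score category")
            ax.set_title(f"Survival by {name} score category")
            path = directory / f"km_{name}.png"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            paths.append(path)
        return paths


def run_full_analysis(
    cohort_dir,
    original_config="original",
    revised_config="revised",
    boundaries: str = "paper",
    revise: bool = False,
    thresholds: RevisionThresholds = RevisionThresholds(),
) -> StudyResults:
    """One-call orchestration on a cohort directory."""
    study = NascherStudy(
        read_cohort(cohort_dir),
        original_config=original_config,
        revised_config="derive" if revise else revised_config,
        boundaries=boundaries,
        revision_thresholds=thresholds,
    )
    return study.fit()
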