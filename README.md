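# nascher

Scoring and evaluation machinery for an additive medical-needs checklist
used in geriatric long-term care, for biostatisticians and study teams
working with nursing-hospital cohorts.

Residents of long-term care nursing hospitals need widely varying
intensities of *medical* (as opposed to nursing) care, and the right
level has to be anticipated at admission.  The instrument modelled here
is an additive checklist assessed at admission: every endorsed item
*j* contributes `w_j` points, so a resident endorsing item set *E*
scores

```
S = min( Σ_{j ∈ E} w_j ,  cap )
```

The packaged **original** configuration has 26 items and a capped range
of 0–20; the packaged **revised** configuration has 12 items (five
2-point items, seven 1-point items) and range 0–17.  Scores are
stratified by quartiles into three categories (lowest quartile, merged
middle quartiles, highest quartile), which enter the survival analysis.

The package implements the full evaluation pipeline:

* **cohort I/O** — CSV tables for residents, admission endorsements and
  dated clinical events, with strict validation
  (`nascher.cohort`);
* **scoring** — configurable additive checklists, quartile
  stratification (`nascher.scoring`);
* **outcomes** — per-resident medical-effort rates: medication changes
  per year, ward-doctor documentations per week, and antibiotic
  episodes per year, where an *episode* is a maximal run of
  antibiotic-administration days not interrupted by ≥ 2 consecutive
  antibiotic-free days (`nascher.outcomes`);
* **revision** — the data-driven re-scoring: drop items endorsed by
  < 5 % of residents, drop inversely associated items, then give 2
  points to items significantly positively rank-correlated with the
  outcomes and 1 point to the rest (`nascher.revision`);
* **statistics** — Spearman correlation, χ², Kruskal–Wallis,
  Kaplan–Meier with median-survival CIs, and mutually adjusted Cox
  proportional-hazards models (`nascher.stats`), exposed through a
  statsmodels-style `NascherStudy` → `StudyResults` pair
  (`nascher.analysis`);
* **synthetic cohorts** — a seeded generator whose latent-severity
  model is calibrated to the published cohort marginals, so the whole
  pipeline is testable without patient data (`nascher.simulate`,
  `nascher.calibrate`).

## Worked example

Generate a synthetic cohort of 396 residents and run the full analysis:

```bash
nascher simulate --seed 1 --out cohort/
nascher run --cohort cohort/ --out report.json --plots plots/
```

which prints (abridged):

```
Cohort: 396 residents; deaths 53.5%
Observation days: median 368 (range 1-1034)

[revised] boundaries <= 4 / >= 8 (paper)
  score mean 7.5 (SD 3.2), median 7, skewness 0.28
  Spearman med_changes_per_year: rho=0.35 (p=8.92e-13)
  Spearman documentations_per_week: rho=0.31 (p=1.44e-10)
  Spearman antibiotic_episodes_per_year: rho=0.22 (p=1.59e-05)
  lowest: n=63, deaths=15 (23.8%), median survival beyond observation
  middle: n=159, deaths=85 (53.5%), median survival 585 d
  highest: n=174, deaths=112 (64.4%), median survival 328 d
  Cox HR category_middle: 2.80 (95% CI 1.61-4.86)
  Cox HR category_highest: 4.20 (95% CI 2.43-7.24)
```

Reading the output: the revised score correlates with all three
medical-effort rates (e.g. Spearman ρ = 0.35 with the annualized
medication-change rate), and mortality rises steeply across score
categories — residents in the highest category die at several times the
rate of the lowest category even after mutual adjustment for sex,
median-split age and median-split care level (the hazard ratios are one
cohort's noisy estimates of the generator's planted contrasts 1.80 and
3.03).  `report.json` carries the complete table set; `plots/` holds
the Kaplan–Meier curves per category.

The same objects are available in Python:

```python
from nascher import NascherStudy, default_params, generate_cohort

study = NascherStudy(generate_cohort(default_params(), seed=1))
results = study.fit()
print(results.summary())
```

Deriving a revised scoring from data instead of using the packaged one:

```bash
nascher revise --cohort cohort/ --out revised.yaml --report revision.json
```

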