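# Methods

This note documents the models and procedures the package implements,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not demonstrate.

## Scoring model

A checklist configuration is a set of items with positive integer
weights and an optional cap; a resident's score is the weighted count
of endorsed items, truncated at the cap.  One endorsement set per
resident is modelled — the assessment at admission; longitudinal
re-scoring is out of scope.

The packaged *original* configuration has 26 items with a cap of 20.
Only nine items are publicly named (geriatric patient, recent acute
event, risk of falls, advanced vascular disease, other cardiovascular
disease, other internal disease, malnutrition, malignancy, and tubes/
implants/cachexia); the remaining 17 are explicit placeholders a site
can replace.  Three common placeholders carry two points so that the
raw sum regularly exceeds the cap: the published original-score
distribution has its entire top quartile at exactly 20 points with a
left-skewed body, which only arises when the cap binds for a sizeable
fraction of residents.  The packaged *revised* configuration has the
five named items most strongly associated with the outcomes at 2
points and seven 1-point items, range 0–17, no cap.

**Category boundaries.**  Scores are stratified into lowest quartile /
merged middle quartiles / highest quartile.  The packaged default
boundaries are the published ones — original: ≤ 14 / 15–19 / ≥ 20,
revised: ≤ 4 / 5–7 / ≥ 8 — because no single standard quantile rule
reproduces them from the published summary statistics.
`derive_category_boundaries` is a documented nearest-rank utility
(Q1/Q3 = smallest value with cumulative proportion ≥ 0.25 / 0.75).  On
a discrete score the naive (Q1, Q3) boundaries can leave the middle
category empty; in that case `high_min` is bumped to Q3 + 1 (and the
lowest boundary dropped to Q1 − 1 when Q1 = Q3).  A sample in which no
adjustment yields three non-empty categories raises a degenerate-
distribution error.

## Outcome operationalization

Three per-resident rates quantify medical effort over the observation
window (admission day through end day, both inclusive, minimum 1 day):

* medication changes per year: `count × 365.25 / days`;
* ward-doctor documentations per week: `count × 7 / days`;
* antibiotic episodes per year: `episodes × 365.25 / days`.

Same-day repeated medication changes count separately (the data model
allows duplicate event rows).  An **antibiotic episode** is a maximal
run of administration days not interrupted by at least two consecutive
antibiotic-free days; formally, scanning deduplicated sorted dates, a
new episode starts whenever `next − previous ≥ 3` days.  A one-day gap
(`next − previous = 2`) continues the episode.  Episodes are counted
purely at calendar level; overlapping different antibiotic substances
are not distinguished.  The year length 365.25 days is a convention
choice.

## Score revision

The revision derives a new two-tier weighting from cohort data, in
order: (1) remove items with endorsement prevalence strictly below 5 %;
(2) remove items whose endorsement is inversely associated with the
outcomes; (3) give 2 points to items significantly positively
associated with the outcomes and 1 point to the rest.  The association
measure is the Spearman rank correlation between the binary endorsement
indicator and each outcome rate, matching the rank-based statistics
used elsewhere in the battery.  "Associated with the outcomes" is a
majority rule: direction or significance (two-sided p < 0.05) on at
least 2 of the 3 outcomes; prevalence threshold, α and the majority
count are all configurable (`RevisionThresholds`).  Zero-variance items
have undefined correlations and fall into the 1-point tier.  No
multiple-testing correction is applied, and the revision is derived and
evaluated on the same cohort — both deliberately mirror the original derivation procedure
and are known limitations, not recommendations.

## Survival and correlation battery

* Spearman correlations use average ranks for ties and the two-sided
  t-approximation for p-values (scipy).
* Contingency tables use Pearson χ² without continuity correction.
* Three-group median comparisons use Kruskal–Wallis with tie
  correction — the natural k-sample rank test where the published
  description specifies only a non-parametric test.
* Kaplan–Meier curves (lifelines) define median survival as the
  smallest time with survival ≤ 0.5, reported as "beyond observation"
  when the curve never reaches 0.5; the 95 % CI of the median comes
  from where the log-log (exponential Greenwood) confidence band
  crosses 0.5, i.e. the Brookmeyer–Crowley construction.
* Cox proportional-hazards fits use the Efron tie correction —
  day-granularity data produce many tied event times — with Wald 95 %
  CIs.  Death (in the facility or after transfer to hospital) is the
  event; discharge and the administrative cutoff censor.  Covariates
  are mutually adjusted indicator terms with references: lowest score
  category, female, at-or-below-median age, at-or-below-median care
  level.  Median splits are strict (`value > median`), so ties with
  the median land in the reference level.  Monotone partial likelihood
  (separation) is detected post-fit (|log HR| > 20 or SE > 100) and
  raised as a convergence error; fits on cohorts with fewer than two
  distinct event times are refused, which the pipeline reports as an
  "insufficient events" marker instead of crashing.
* No proportional-hazards diagnostic gates the fits; estimates are
  reported as specified.

## Synthetic cohort model

The generator emulates a two-facility admission cohort: 396 residents
admitted uniformly over 2020-08-01 … 2022-07-31, observed until death,
discharge, or the administrative cutoff 2023-05-31.

A single latent severity factor `z ~ N(0, 1)` drives everything
resident-specific:

* **endorsement**: item *j* is endorsed with probability
  `expit(α_j + λ_j z)`;
* **counts**: each outcome's expected count is
  `exp(a_0 + a_1 z) · days / period` with negative-binomial dispersion
  (Poisson–gamma mixture), reproducing the strongly right-skewed
  published rate distributions (e.g. mean 40.6 vs median 16.3
  medication changes per year);
* **survival**: death is exponential with hazard `h_0 · θ(category)`,
  where the category comes from the revised score at the packaged
  boundaries (4, 8) and the planted contrasts are θ_middle = 1.80,
  θ_highest = 3.03 — exactly the published adjusted hazard ratios, so
  the Cox analysis is a clean parameter-recovery exercise.  Discharge
  is an independent exponential censoring process; sex, age and care
  level are independent of `z`, so the adjusted covariates are true
  null effects.
* **events**: medication changes and documentations are dated uniformly
  in the window; antibiotic administrations are materialized as runs of
  3–10 consecutive days separated by ≥ 3 free days (episode counts are
  reduced when a short window cannot hold them), so the episode
  segmentation rule reconstructs the planted count exactly — a strict
  round-trip invariant of the test suite.

**Calibration** (`nascher.calibrate`, frozen into
`configs/generator_defaults.yaml`, reproducible via
`nascher calibrate`): item intercepts are solved by Gauss–Hermite
quadrature of the logistic-normal marginal against the published item
prevalences (placeholder prevalences are design choices, including two
rare items below the pruning threshold and two inversely loaded items
so the revision's pruning steps are exercised); the two hazards are
bisected at n = 10,000 against the published death fraction (51.5 %)
and discharge fraction (10.6 %); each outcome's log-baseline and
severity loading are bisected alternately against the published median
rate and a target score–rate Spearman correlation.  The
medication-change correlation target is the published 0.36; the
documentation and antibiotic targets (0.30, 0.28) are design choices
slightly above the published 0.26/0.21, chosen so that the five
strongly loaded items remain individually detectable at n = 396 and
the planted two-tier structure is recoverable — the stated recovery
property of the generator.  Severity loadings (2.5 for the five
two-point items, 0.4/0.3/0.1 tiers below, −0.8 for the inverse
placeholders) and NB dispersions (0.55, 2.0, 0.9) are design constants.

**Known deviation from the printed tables.**  The published item
prevalences combined with the revised two-point weighting force a mean
revised score around 7.7; the published mean is 5.9 — an internal
inconsistency of the printed tables (its own top-quartile boundary 8
with IQR 4–7 shows a similar tension).  The generator honours the
prevalence, correlation and death-fraction targets; consequently the
(4, 8) boundaries stratify roughly 14 / 56 / 30 % instead of
25 / 50 / 25 %, and the small lowest (reference) category makes
per-cohort hazard-ratio estimates noisier than a true quartile split
would.

**What the generator does not emulate**: no diagnoses, medications or
facility structure; no longitudinal re-assessment; no seasonality or
calendar trends; covariates independent of severity (so the synthetic
cohorts cannot demonstrate confounding control, only adjustment
mechanics); constant hazards (no survival-shape information was
available beyond KM medians).  Passing tests therefore show the
pipeline's correctness and calibration on a faithful statistical
caricature, not clinical realism.

## Problem sizes and reproducibility

The test suite exercises ten default cohorts (seeds 1–10, n = 396
each) for calibration-adequacy and hazard-recovery checks, 50 cohorts
for the revision-recovery experiments, 1,000 null replicates for the
Kruskal–Wallis size check and 50 replicates at n = 2,000 for the Cox
null-covariate check.  `scripts/acceptance.py` regenerates 80 replicate
cohorts (seeds derived from `--seed` via a seed sequence) and combines
per-cohort hazard ratios as the geometric mean — the arithmetic mean of
noisy ratio estimates is inflated by Jensen's inequality, whereas the
log scale is the natural scale of the estimator.  All randomness is
seeded; identical parameters and seed give byte-identical cohort files.

## Limitations

* The true 26-item list and its weighting are not public; placeholders
  make the packaged original configuration structurally, not
  clinically, faithful.
* The revision procedure's "significant association with the outcomes"
  is an explicit, configurable operationalization of an informally
  stated rule.
* Discharge is treated as plain censoring (no competing-risks model),
  and no sensitivity/specificity analysis is provided, matching the
  scope of the original evaluation.
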