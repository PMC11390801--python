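n_residents: 396
admission_window:
- '2020-08-01'
- '2022-07-31'
cutoff_date: '2023-05-31'
male_fraction: 0.434
age_mean: 81.2
age_sd: 10.8
age_bounds:
- 40.0
- 104.0
care_level_probs:
- 0.01
- 0.02
- 0.07
- 0.18
- 0.32
- 0.24
- 0.11
- 0.05
items:
  geriatric_patient:
    intercept: 4.356555
    loading: 2.5
  recent_acute_event:
    intercept: 2.807807
    loading: 2.5
  risk_of_falls:
    intercept: 1.42035
    loading: 0.4
  advanced_vascular_disease:
    intercept: 0.534564
    loading: 0.4
  other_cardiovascular_disease:
    intercept: -0.326605
    loading: 0.4
  other_internal_disease:
    intercept: -0.360727
    loading: 0.4
  malnutrition:
    intercept: -1.356891
    loading: 2.5
  malignancy:
    intercept: -1.980443
    loading: 2.5
  tubes_implants_or_cachexia:
    intercept: -2.658235
    loading: 2.5
  placeholder_10:
    intercept: -2.232934
    loading: 0.3
  placeholder_11:
    intercept: -2.026308
    loading: 0.3
  placeholder_12:
    intercept: -1.765745
    loading: 0.3
  placeholder_13:
    intercept: -3.89182
    loading: 0.0
  placeholder_14:
    intercept: -3.178054
    loading: 0.0
  placeholder_15:
    intercept: -0.962064
    loading: -0.8
  placeholder_16:
    intercept: -1.243328
    loading: -0.8
  placeholder_17:
    intercept: 3.480797
    loading: 0.1
  placeholder_18:
    intercept: 3.182652
    loading: 0.1
  placeholder_19:
    intercept: 2.948937
    loading: 0.1
  placeholder_20:
    intercept: 2.755933
    loading: 0.1
  placeholder_21:
    intercept: 2.590987
    loading: 0.1
  placeholder_22:
    intercept: 2.446544
    loading: 0.1
  placeholder_23:
    intercept: 2.201221
    loading: 0.1
  placeholder_24:
    intercept: 1.996226
    loading: 0.1
  placeholder_25:
    intercept: 1.738097
    loading: 0.1
  placeholder_26:
    intercept: 1.38929
    loading: 0.1
counts:
  med_changes:
    log_baseline: 3.644518
    severity: 0.97857
    dispersion: 0.55
    period_days: 365.25
  documentations:
    log_baseline: 0.812015
    severity: 0.334825
    dispersion: 2.0
    period_days: 7.0
  antibiotic_episodes:
    log_baseline: 1.078872
    severity: 0.700732
    dispersion: 0.9
    period_days: 365.25
hazards:
  baseline_death_hazard: 0.000592731
  discharge_hazard: 0.000271106
  theta_middle: 1.8
  theta_highest: 3.03
  died_in_hospital_fraction: 0.14215686274509803
  discharge_probs:
  - 0.6904761904761905
  - 0.11904761904761904
  - 0.19047619047619047
category_boundaries:
  low_max: 4
  high_min: 8
scoring_config: revised
seed: null
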