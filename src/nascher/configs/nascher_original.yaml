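# Original 26-item medical-needs checklist, total capped at 20.  Most
# items carry one point; three common placeholder items carry two, so the
# raw sum regularly exceeds the cap and the capped score shows the
# documented pile-up at 20 (the published top quartile is exactly 20
# points) with a left-skewed distribution.  Only the nine items named in
# the published evaluation are identified here; placeholder_10..26 stand
# in for the remaining items of the routine instrument and should be
# replaced by a site that holds the full item list (the scoring
# machinery is agnostic to item names).
name: original
cap: 20
items:
  - {name: geriatric_patient, points: 1, domain: geriatric_patient}
  - {name: recent_acute_event, points: 1, domain: medical_incident_risk}
  - {name: risk_of_falls, points: 1, domain: medical_incident_risk}
  - {name: advanced_vascular_disease, points: 1, domain: advanced_chronic_disease}
  - {name: other_cardiovascular_disease, points: 1, domain: advanced_chronic_disease}
  - {name: other_internal_disease, points: 1, domain: advanced_chronic_disease}
  - {name: malnutrition, points: 1, domain: geriatric_patient}
  - {name: malignancy, points: 1, domain: advanced_chronic_disease}
  - {name: tubes_implants_or_cachexia, points: 1, domain: special_measures}
  - {name: placeholder_10, points: 1, domain: null}
  - {name: placeholder_11, points: 1, domain: null}
  - {name: placeholder_12, points: 1, domain: null}
  - {name: placeholder_13, points: 1, domain: null}
  - {name: placeholder_14, points: 1, domain: null}
  - {name: placeholder_15, points: 1, domain: null}
  - {name: placeholder_16, points: 1, domain: null}
  - {name: placeholder_17, points: 2, domain: null}
  - {name: placeholder_18, points: 2, domain: null}
  - {name: placeholder_19, points: 2, domain: null}
  - {name: placeholder_20, points: 1, domain: null}
  - {name: placeholder_21, points: 1, domain: null}
  - {name: placeholder_22, points: 1, domain: null}
  - {name: placeholder_23, points: 1, domain: null}
  - {name: placeholder_24, points: 1, domain: null}
  - {name: placeholder_25, points: 1, domain: null}
  - {name: placeholder_26, points: 1, domain: null}
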