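# Revised 12-item scoring: the five items most strongly associated with
# the medical-needs outcomes carry two points, the remaining seven one
# point; no cap, maximum 17.  Three one-point slots are placeholders
# mirroring the original configuration's unnamed items.
name: revised
items:
  - {name: geriatric_patient, points: 2, domain: geriatric_patient}
  - {name: malnutrition, points: 2, domain: geriatric_patient}
  - {name: tubes_implants_or_cachexia, points: 2, domain: special_measures}
  - {name: recent_acute_event, points: 2, domain: medical_incident_risk}
  - {name: malignancy, points: 2, domain: advanced_chronic_disease}
  - {name: risk_of_falls, points: 1, domain: medical_incident_risk}
  - {name: advanced_vascular_disease, points: 1, domain: advanced_chronic_disease}
  - {name: other_cardiovascular_disease, points: 1, domain: advanced_chronic_disease}
  - {name: other_internal_disease, points: 1, domain: advanced_chronic_disease}
  - {name: placeholder_10, points: 1, domain: null}
  - {name: placeholder_11, points: 1, domain: null}
  - {name: placeholder_12, points: 1, domain: null}
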