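# Demonstration cause list (~20 causes). Illustrative only: a national list
# would run to around two hundred specific diseases.
causes:
  - id: chd
    name: Coronary heart disease
    group: cardiovascular
    icd10: ["I20-I25"]
  - id: stroke
    name: Stroke
    group: cardiovascular
    icd10: ["I60-I64"]
  - id: heart_failure
    name: Heart failure and cardiomyopathy
    group: cardiovascular
    icd10: ["I42", "I50"]
  - id: lung_ca
    name: Lung cancer
    group: cancer
    icd10: ["C33-C34"]
  - id: colorectal_ca
    name: Colorectal cancer
    group: cancer
    icd10: ["C18-C20"]
  - id: breast_ca
    name: Breast cancer
    group: cancer
    icd10: ["C50"]
  - id: pancreatic_ca
    name: Pancreatic cancer
    group: cancer
    icd10: ["C25"]
  - id: cup
    name: Cancer of unknown primary site
    group: cancer
    icd10: ["C80"]
    redistribution_source: true
  - id: unspec_ca
    name: Cancer of other and ill-defined sites
    group: cancer
    icd10: ["C76"]
    redistribution_source: true
  - id: copd
    name: Chronic obstructive pulmonary disease
    group: respiratory
    icd10: ["J40-J44"]
  - id: pneumonia
    name: Lower respiratory infections
    group: respiratory
    icd10: ["J12-J18"]
  - id: diabetes
    name: Diabetes mellitus
    group: endocrine
    icd10: ["E10-E14"]
  - id: dementia
    name: Dementia including Alzheimer disease
    group: neurological
    icd10: ["F00-F03", "G30"]
  - id: sepsis
    name: Septicaemia
    group: infections
    icd10: ["A40-A41"]
    redistribution_source: true
  - id: other_infections
    name: Other infectious diseases
    group: infections
    icd10: ["A00-A39", "A42-A99", "B00-B99"]
  - id: falls
    name: Falls
    group: injuries
    icd10: ["W00-W19"]
  - id: road_injury
    name: Road traffic injuries
    group: injuries
    icd10: ["V01-V89"]
  - id: suicide
    name: Suicide and self-inflicted injuries
    group: injuries
    icd10: ["X60-X84"]
  - id: low_back_pain
    name: Back pain and problems
    group: musculoskeletal
    icd10: ["M54"]
  - id: anxiety
    name: Anxiety disorders
    group: mental
    icd10: ["F40-F41"]
  - id: depression
    name: Depressive disorders
    group: mental
    icd10: ["F32-F33"]
  - id: ill_defined
    name: Symptoms, signs and ill-defined conditions
    group: ill-defined
    icd10: ["R00-R99"]
    redistribution_source: true
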