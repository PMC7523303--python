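# Demonstration disease conceptual models: sequelae, severity splits and
# disability weights (values in the range published weight sets use;
# illustrative, not a published set).
models:
  - disease: chd
    sequelae:
      - id: chd_angina
        levels:
          - {name: mild, proportion: 0.55, disability_weight: 0.033}
          - {name: moderate, proportion: 0.30, disability_weight: 0.080}
          - {name: severe, proportion: 0.15, disability_weight: 0.167}
      - id: chd_post_ami
        levels:
          - {name: acute, proportion: 1.0, disability_weight: 0.432}
  - disease: stroke
    sequelae:
      - id: stroke_longterm
        levels:
          - {name: mild, proportion: 0.45, disability_weight: 0.019}
          - {name: moderate, proportion: 0.35, disability_weight: 0.070}
          - {name: severe, proportion: 0.20, disability_weight: 0.552}
  - disease: copd
    sequelae:
      - id: copd_symptomatic
        levels:
          - {name: mild, proportion: 0.50, disability_weight: 0.019}
          - {name: moderate, proportion: 0.35, disability_weight: 0.225}
          - {name: severe, proportion: 0.15, disability_weight: 0.408}
  - disease: diabetes
    sequelae:
      - id: diabetes_uncomplicated
        levels:
          - {name: controlled, proportion: 0.80, disability_weight: 0.049}
          - {name: with_neuropathy, proportion: 0.20, disability_weight: 0.133}
  - disease: dementia
    sequelae:
      - id: dementia_cases
        levels:
          - {name: mild, proportion: 0.40, disability_weight: 0.069}
          - {name: moderate, proportion: 0.35, disability_weight: 0.377}
          - {name: severe, proportion: 0.25, disability_weight: 0.449}
  - disease: low_back_pain
    sequelae:
      - id: lbp_episodes
        levels:
          - {name: mild, proportion: 0.60, disability_weight: 0.020}
          - {name: moderate, proportion: 0.30, disability_weight: 0.054}
          - {name: severe, proportion: 0.10, disability_weight: 0.325}
  - disease: anxiety
    sequelae:
      - id: anxiety_cases
        levels:
          - {name: mild, proportion: 0.55, disability_weight: 0.030}
          - {name: moderate, proportion: 0.30, disability_weight: 0.133}
          - {name: severe, proportion: 0.15, disability_weight: 0.523}
  - disease: depression
    sequelae:
      - id: depression_cases
        levels:
          - {name: mild, proportion: 0.50, disability_weight: 0.145}
          - {name: moderate, proportion: 0.35, disability_weight: 0.396}
          - {name: severe, proportion: 0.15, disability_weight: 0.658}
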