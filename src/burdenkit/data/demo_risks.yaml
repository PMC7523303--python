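# Demonstration risk-outcome pairs (categorical exposures, RR = 1 at the
# theoretical-minimum category; one pair uses direct evidence).
risks:
  - risk: tobacco
    outcome: lung_ca
    tmred: never
    rr: {never: 1.0, former: 3.5, current: 12.0}
    exposure: {never: 0.62, former: 0.24, current: 0.14}
  - risk: tobacco
    outcome: copd
    tmred: never
    rr: {never: 1.0, former: 2.8, current: 6.5}
    exposure: {never: 0.62, former: 0.24, current: 0.14}
  - risk: high_bmi
    outcome: chd
    tmred: normal
    rr: {normal: 1.0, overweight: 1.3, obese: 1.9}
    exposure: {normal: 0.37, overweight: 0.36, obese: 0.27}
  - risk: high_bmi
    outcome: diabetes
    tmred: normal
    rr: {normal: 1.0, overweight: 2.4, obese: 6.0}
    exposure: {normal: 0.37, overweight: 0.36, obese: 0.27}
  - risk: alcohol
    outcome: road_injury
    tmred: none
    rr: {none: 1.0, low: 1.2, high: 4.5}
    exposure: {none: 0.55, low: 0.35, high: 0.10}
  # Direct evidence overriding the modelled fraction (the exposure/RR are
  # retained only for scenario analysis).
  - risk: intimate_partner_violence
    outcome: suicide
    tmred: unexposed
    rr: {unexposed: 1.0, exposed: 2.3}
    exposure: {unexposed: 0.83, exposed: 0.17}
    direct_fraction: 0.12
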