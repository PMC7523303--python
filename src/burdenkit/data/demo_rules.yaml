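# Demonstration redistribution rules exercising all four methods.
rules:
  # Registry-linkage style direct evidence: most unknown-primary deaths are
  # genuine, the remainder are better allocated to specific sites.
  - source: cup
    method: direct
    table:
      cup: 0.70
      lung_ca: 0.12
      colorectal_ca: 0.09
      pancreatic_ca: 0.09

  # Cascade: ill-defined cancer sites resolve partly to unknown-primary
  # (handled by the rule above) and partly straight to specific sites.
  - source: unspec_ca
    method: direct
    table:
      cup: 0.30
      lung_ca: 0.25
      colorectal_ca: 0.20
      breast_ca: 0.15
      pancreatic_ca: 0.10

  # Septicaemia as underlying cause: a stated share through a direct table,
  # the remainder via the associated-cause (indirect MCOD) pattern.
  - source: sepsis
    method: combination
    direct_share: 0.15
    table:
      pneumonia: 0.50
      other_infections: 0.30
      chd: 0.20

  # Symptom/ill-defined chapter: low-volume proportional fallback across a
  # stated target set, split by the observed underlying-cause distribution.
  - source: ill_defined
    method: proportional
    targets: [chd, stroke, copd, dementia, falls]
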