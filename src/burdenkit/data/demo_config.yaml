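# Demonstration pipeline configuration. Paths are resolved relative to this
# file; "builtin:" entries use the deterministic synthetic tables shipped in
# code.
seed: 20150701
out_dir: out

cause_list: demo_causes.yaml
rules: demo_rules.yaml
disease_models: demo_models.yaml
risks: demo_risks.yaml
quality_ratings: demo_quality_ratings.csv
life_table: builtin
population_life_table: builtin

simulation:
  n_deaths: 20000
  garble_fraction: 0.105
  assoc_mention_prob: 0.9
  source_mention_prob: 0.25
  age_mean: 78.0
  age_sd: 13.0
  female_fraction: 0.5
  garble_targets: {sepsis: 0.40, ill_defined: 0.30, cup: 0.20, unspec_ca: 0.10}
  true_cause_distribution:
    chd: 0.16
    stroke: 0.08
    heart_failure: 0.04
    lung_ca: 0.08
    colorectal_ca: 0.05
    breast_ca: 0.03
    pancreatic_ca: 0.03
    copd: 0.08
    pneumonia: 0.05
    diabetes: 0.05
    dementia: 0.13
    other_infections: 0.04
    falls: 0.06
    road_injury: 0.04
    suicide: 0.04
    low_back_pain: 0.01
    anxiety: 0.01
    depression: 0.02

prevalence:
  median: 1200.0
  sigma: 0.4
  age_groups: ["0-4", "5-14", "15-44", "45-64", "65-84", "85+"]

hale:
  # per-person morbidity (YLD per capita) by single year of age:
  # rate = base + slope * age, capped
  base: 0.02
  slope: 0.0016
  cap: 0.25
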