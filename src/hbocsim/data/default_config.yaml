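# Default run configuration: anchor-calibrated BRCA1/2 penetrance, the two
# named screening scenarios, and a truncated-normal simulation population.
schema_version: 1
seed: 0
start_age: 25
anchors:
  BRCA1:
    breast: [{age: 70, risk: 0.57}]
    ovarian: [{age: 70, risk: 0.40}]
  BRCA2:
    breast: [{age: 70, risk: 0.49}]
    ovarian: [{age: 70, risk: 0.18}]
carrier_frequencies:
  BRCA1: 0.00058
  BRCA2: 0.00068
age_distribution:
  model: truncnorm   # truncnorm | uniform | csv
  n_women: 186537
  mean: 52.0
  sd: 12.0
  # csv: path/to/age_counts.csv   (columns: age, count)
horizons: [30, 40]
scenarios:
  underserved:
    detection_rate: 0.235
    mastectomy_uptake: 0.25
    oophorectomy_uptake: 0.40
  insured:
    detection_rate: 0.766
    mastectomy_uptake: 0.405
    oophorectomy_uptake: 0.71
microsim:
  n_women: 200000
# cascade_fixtures: [list of CSV paths]; defaults to the packaged fixtures
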