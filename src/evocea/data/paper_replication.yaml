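# Replication configuration: published point estimates as inputs.
# Cohort marginals follow the source sample (n = 61); monetary values are
# 2017 BRL written as decimal strings.
cohort:
  n: 61
  seed: 1
translation:
  ldl_reduction_fraction: 0.59
  rrr_per_block: 0.21
  block_size: 39.0
  scaling: linear
  rounding: paper
costs:
  c_mi: "588.12"
  c_stroke: "463.21"
  c_revasc: "6756.37"
  atorvastatin_tablet_40mg: "1.00"
  evolocumab_syringe_140mg: "901.61"
  annual_income_adjusted: "22128.00"
  currency_year: 2017
regimen_a:
  name: atorvastatin
  atorvastatin_tablets_per_day: 2.0
  evolocumab_doses_per_year: 0.0
  horizon: 10.0
regimen_b:
  name: atorvastatin+evolocumab
  atorvastatin_tablets_per_day: 2.0
  evolocumab_doses_per_year: 24.0   # calendar reading of one dose every 15 days
  horizon: 10.0
death:
  mean_age: 63.0
  mean_age_at_death: 68.0
  life_expectancy: 75.6666666666666666
  rounding_yll: 1
markov:
  horizon_cycles: 10
  cycle_length: 1.0
  discount_rate: 0.05
  effectiveness_definition: event_free_at_horizon
  half_cycle_correction: false
  allow_recurrence: true
psa:
  n_draws: 1000
  seed: 0
  rel_halfwidth: 0.20
dsa:
  fraction: 0.20
replication_overrides:
  baseline_risk_10y: 35.0
  mean_ldl: 111.0
  strategy_a: {cost: "46522.44", effectiveness: 0.54}
  strategy_b: {cost: "236141.85", effectiveness: 0.73}
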