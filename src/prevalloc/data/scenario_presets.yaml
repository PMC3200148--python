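# Scenario presets for the sensitivity analyses (YAML form of
# prevalloc.sensitivity presets; load with sensitivity.load_scenarios).
# Scenarios with rate_health / rate_cost / horizon keys re-simulate every
# cell and therefore need a cohort configuration, not a static problem.
- label: with capacity constraints
  capacities_active: true
- label: without capacity constraints
  capacities_active: false
- label: discount 0%/0%
  rate_health: 0.0
  rate_cost: 0.0
  horizon: lifetime
- label: base case 1.5%/4%
  rate_health: 0.015
  rate_cost: 0.04
  horizon: lifetime
- label: discount 4%/4%
  rate_health: 0.04
  rate_cost: 0.04
  horizon: lifetime
- label: health 0%, costs 4%
  rate_health: 0.0
  rate_cost: 0.04
  horizon: lifetime
- label: horizon 25y
  rate_health: 0.015
  rate_cost: 0.04
  horizon: 25
- label: horizon 50y
  rate_health: 0.015
  rate_cost: 0.04
  horizon: 50
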