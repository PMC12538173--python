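schema_version: 1
currency: EUR
price_year: 2019
horizon: 10.0
wtp: 50000.0
relapse_split_mode: episode_type_model
active_utilities: patient_TTO
transitions:
  relapse:
    from_state: out_of_episode
    to_state: null
    family: exponential
    rate: 0.4
    psa_se:
      rate: 0.05
  remission:
    from_state: episode_outpatient
    to_state: out_of_episode
    family: exponential
    rate: 2.0
    psa_se:
      rate: 0.05
  death_out:
    from_state: out_of_episode
    to_state: dead
    family: exponential
    rate: 0.007
    psa_se:
      rate: 0.1
  death_episode:
    from_state: episode_outpatient
    to_state: dead
    family: exponential
    rate: 0.012
    psa_se:
      rate: 0.1
episode_type:
  intercept: -0.8472978603872036
  coefficients: {}
  intercept_se: 0.05
  coefficient_se: {}
utility_sets:
  patient_TTO:
    provenance: patient_TTO
    values:
      out_of_episode:
        value: 0.92
        se: 0.03
      episode_outpatient:
        value: 0.76
        se: 0.05
      episode_inpatient:
        value: 0.6
        se: 0.05
  lay_TTO:
    provenance: lay_TTO
    values:
      out_of_episode:
        value: 0.9
        se: 0.03
      episode_outpatient:
        value: 0.7
        se: 0.06
      episode_inpatient:
        value: 0.5
        se: 0.06
cost_equation:
  intercepts:
    out_of_episode: 7.600902459542082
    episode_outpatient: 9.615805480084347
    episode_inpatient: 11.002099841204238
  coefficients: {}
  sojourn_time_coefficient: 0.0
  intercept_se:
    out_of_episode: 0.05
    episode_outpatient: 0.05
    episode_inpatient: 0.05
  coefficient_se: {}
intervention_cost:
  n_sessions: 16
  unit_cost: 108.22
  group_size: 1
treatment_effect:
  rr: 0.79
  ci_low: 0.6
  ci_high: 1.04
  duration: 2.0
  target: all_relapse
  direct_utility_bonus: 0.0
discount:
  rate_costs: 0.035
  rate_effects: 0.035
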