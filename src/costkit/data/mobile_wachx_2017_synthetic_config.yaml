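discount_rate: 0.03
equipment_life_years: 10.0
startup_life_years: 5.0
exchange_rate_kes_per_usd: 103.25
startup_amortization: straight_line
rounding: half_up
project_total_clients: 548
economics:
  incremental_cost_usd: 7084.0
  effects:
  - label: viral_load_suppression
    incremental_effect_count: 11
    source: two-way SMS RCT in Kenyan HIV clinics
  - label: medication_adherence
    incremental_effect_count: 15
    source: meta-analysis of SMS adherence interventions
  projection:
    target_population: 59000
    penetration: 0.8
    reference_budget_usd: 46000000.0
scenarios:
  scale6:
    arm: two_way
    facility_beneficiaries:
      facility_A: 152
      facility_B: 80
      facility_C: 79
      facility_D: 79
      facility_E: 79
      facility_F: 79
    template_facility: facility_A
    salary_table: null
    config_overrides:
      project_total_clients: null
  moh:
    arm: two_way
    facility_beneficiaries:
      facility_A: 152
      facility_B: 80
      facility_C: 79
      facility_D: 79
      facility_E: 79
      facility_F: 79
    template_facility: facility_A
    salary_table:
      study_nurse: 6276.391284029105
      retention_officer: 3138.1956420145525
    config_overrides:
      project_total_clients: null
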