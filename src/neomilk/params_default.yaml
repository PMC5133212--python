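# neomilk model configuration.
# cohort.band_shares (birthweight-band mix of the cohort) is an
# assumption, not a published input: it is the principal free
# parameter of the model.
# age_utility.utility is calibrated so qaly_loss_per_death
# rebuilds to 23.6 at the default discount rate.
cohort:
  n_preterm: 51703
  band_shares:
  - 0.04
  - 0.1
  - 0.36
  - 0.5
  discount_rate: 0.035
  wtp_per_qaly: 20000.0
  lifetime_earnings_low: 540500.0
  lifetime_earnings_mid: 645500.0
  lifetime_earnings_high: 750500.0
  qaly_loss_per_death: 23.6
base_scenario:
  exclusive_hm_rate: 0.35
  any_hm_rate: 0.35
  label: base_case_35pct
counterfactual_scenario:
  exclusive_hm_rate: 1.0
  any_hm_rate: 1.0
  label: counterfactual_100pct
nicu_outcomes:
  medical_nec:
    name: medical_nec
    incidence_by_band:
    - 0.035
    - 0.021
    - 0.005
    - 0.0
    or_exclusive_vs_mixed: 0.412
    or_formula_vs_mixed: 3.006
    los_days: 27.2
    cost_per_day: 630.08
    fixed_cost: 0.0
    cost_includes: null
    mortality_or: 2.055
    ndi_or: 1.187
    reference_arm: mixed_arm
  surgical_nec:
    name: surgical_nec
    incidence_by_band:
    - 0.033
    - 0.006
    - 0.001
    - 0.0
    or_exclusive_vs_mixed: 0.412
    or_formula_vs_mixed: 3.006
    los_days: 0.0
    cost_per_day: 630.08
    fixed_cost: 1739.0
    cost_includes: medical_nec
    mortality_or: 3.124
    ndi_or: 1.985
    reference_arm: mixed_arm
  sepsis:
    name: sepsis
    incidence_by_band:
    - 0.272
    - 0.082
    - 0.047
    - 0.0
    or_exclusive_vs_mixed: 0.707
    or_formula_vs_mixed: 0.803
    los_days: 5.9
    cost_per_day: 630.08
    fixed_cost: 0.0
    cost_includes: null
    mortality_or: 3.219
    ndi_or: 2.282
    reference_arm: mixed_arm
mortality:
  baseline_nicu_mortality_by_band:
  - 0.205
  - 0.08
  - 0.05
  - 0.0
postdischarge:
  sids:
    name: sids
    baseline_incidence: 0.0007
    or_any_hm_vs_formula: 0.4
    cost_per_case: 72.0
    is_fatal: true
    survival_rate: null
    on_treatment_utility: null
    treatment_years: null
    diagnosis_age: null
    reference_arm: population_mix
  aom:
    name: aom
    baseline_incidence: 0.0014
    or_any_hm_vs_formula: 0.4
    cost_per_case: 46.0
    is_fatal: false
    survival_rate: null
    on_treatment_utility: null
    treatment_years: null
    diagnosis_age: null
    reference_arm: population_mix
  leukaemia:
    name: leukaemia
    baseline_incidence: 0.0004
    or_any_hm_vs_formula: 0.91
    cost_per_case: 114456.0
    is_fatal: false
    survival_rate: 0.92
    on_treatment_utility: 0.66
    treatment_years: 2.0
    diagnosis_age: 5.0
    reference_arm: population_mix
obesity:
  child_obesity_rate: 0.095
  or_any_hm_vs_formula: 0.79
  p_obese_adult_given_obese_child: 0.65
  t2d_prevalence_in_obese: 0.0961
  chd_prevalence_in_obese: 0.0604
  t2d_annual_cost: 787.0
  chd_annual_cost: 1974.0
  t2d_diagnosis_age: 55.0
  chd_diagnosis_age: 65.0
  end_age: 75.0
  t2d_utility: 0.866
  chd_utility: 0.867
  reference_arm: population_mix
ndi:
  incidence_by_band:
  - 0.49
  - 0.41
  - 0.34
  - 0.0
  severity_split:
  - 0.65
  - 0.22
  - 0.14
  lifetime_cost:
  - 14421.0
  - 13959.0
  - 365005.0
  life_expectancy:
  - 78.5
  - 67.8
  - 26.1
  utility:
  - 0.85
  - 0.645
  - 0.47
  healthy_life_expectancy: 78.5
age_utility:
  life_expectancy: 81.0
  utility: 0.880255
comparator_utility: 1.0
survivors_only: false
dsa_ranges: []
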