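# Base-case configuration: parameter inputs of the dynamic-adherence asthma
# Markov model. Monetary values are 2014 USD; probabilities are monthly.
model:
  start_age: 50
  max_age: 105
  cycle_length_months: 1
  annual_discount_rate: 0.03
  willingness_to_pay: 9006.0
  # The starting mix over B/C/D of the original clinic cohort is unknown;
  # equal thirds is the declared uninformative default.
  initial_distribution:
    B: 0.3333333333333333
    C: 0.3333333333333333
    D: 0.3333333333333334
  psa_draws: 10000
  random_seed: 20140322
  utility_set: base_case
  effectiveness: asthma_control
  half_cycle_correction: false
  hospitalization_metric: entries   # entries | occupancy_months

effect:
  mode: zhang_yu_rr                 # zhang_yu_rr | exact_odds
  reference_risk: rmtac_row_probability

classification:
  act_poor_max: 19                  # ACT <= 19 is poor control
  adherence_low_below: 6.0          # adherence score < 6 is low adherence

# Monthly transition probabilities between states A-D under RMTAC + UC.
base_transitions:
  distribution: dirichlet
  dirichlet_n_eff: 16
  A:
    B: {value: 0.122, low: 0.03365, high: 0.35673}
    C: {value: 0.152, low: 0.04763, high: 0.39112}
    D: {value: 0.030, low: 0.00304, high: 0.23896}
  B:
    A: {value: 0.382, low: 0.18072, high: 0.63454}
    C: {value: 0.032, low: 0.00306, high: 0.26248}
    D: {value: 0.058, low: 0.00895, high: 0.29784}
  C:
    A: {value: 0.184, low: 0.08224, high: 0.36201}
    B: {value: 0.008, low: 0.00042, high: 0.13430}
    D: {value: 0.043, low: 0.00867, high: 0.18760}
  D:
    A: {value: 0.088, low: 0.01812, high: 0.33530}
    B: {value: 0.051, low: 0.00708, high: 0.28827}
    C: {value: 0.088, low: 0.01812, high: 0.33530}

effectiveness_factors:
  asthma_control:
    odds_ratio: {value: 3.059, low: 1.632, high: 5.733, dist: lognormal}
    target_states: [A, B]
  medication_adherence:
    odds_ratio: {value: 1.89, low: 1.08, high: 3.30, dist: lognormal}
    target_states: [A, C]

exacerbation:
  # low-adherence monthly exacerbation probabilities
  p_BE: {value: 0.09273, low: 0.07489, high: 0.11021, dist: beta}
  p_BF: {value: 0.00412, low: 0.00330, high: 0.00495, dist: beta}
  p_DE: {value: 0.23237, low: 0.19068, high: 0.27191, dist: beta}
  p_DF: {value: 0.05390, low: 0.04335, high: 0.06432, dist: beta}
  # hazard ratios for high-adherence patients, by control level
  hr_good_control: {value: 0.72, low: 0.34, high: 1.51, dist: lognormal}
  hr_poor_control: {value: 0.59, low: 0.37, high: 0.95, dist: lognormal}
  # post-exacerbation monthly recovery probabilities
  p_EA: {value: 0.02528, low: 0.01962, high: 0.03132, dist: beta}
  p_EC: {value: 0.10484, low: 0.07127, high: 0.16332, dist: beta}
  p_FA: {value: 0.02394, low: 0.01862, high: 0.02961, dist: beta}
  p_FC: {value: 0.10738, low: 0.07261, high: 0.16990, dist: beta}
  # re-exacerbation after a recent exacerbation (shared value, tied in PSA)
  p_EF: {value: 0.047, low: 0.0376, high: 0.0564, dist: beta}
  p_FE: {value: 0.047, low: 0.0376, high: 0.0564, dist: beta}
  # asthma mortality after a non-hospitalized exacerbation
  p_EG: {value: 0.000059, low: 0.000048, high: 0.000071, dist: beta}

utilities:
  base_case:
    A: {value: 0.5583, low: 0.4435, high: 0.6731, dist: beta}
    B: {value: 0.5583, low: 0.4435, high: 0.6731, dist: beta}
    C: {value: 0.5316, low: 0.3788, high: 0.6844, dist: beta}
    D: {value: 0.5316, low: 0.3788, high: 0.6844, dist: beta}
    E: {value: 0.5311, low: 0.4254, high: 0.6368, dist: beta}
    F: {value: 0.3842, low: 0.2882, high: 0.4802, dist: beta}
  psa_alternative:
    A: {value: 0.5598, low: 0.4588, high: 0.6608, dist: beta}
    B: {value: 0.5598, low: 0.4588, high: 0.6608, dist: beta}
    C: {value: 0.5316, low: 0.3788, high: 0.6844, dist: beta}
    D: {value: 0.5316, low: 0.3788, high: 0.6844, dist: beta}
    E: {value: 0.4514, low: 0.3589, high: 0.5439, dist: beta}
    F: {value: 0.2919, low: 0.2091, high: 0.3747, dist: beta}

costs:
  c_A: {value: 38.78, low: 33.77, high: 43.78, dist: gamma}
  c_B: {value: 39.70, low: 34.70, high: 44.71, dist: gamma}
  c_C: {value: 42.48, low: 37.46, high: 47.50, dist: gamma}
  c_D: {value: 38.67, low: 35.62, high: 45.64, dist: gamma}
  c_E: {value: 13.50, low: 12.53, high: 14.46, dist: lognormal}
  c_F: {value: 552.13, low: 468.03, high: 636.23, dist: gamma}
  rmtac_recruitment: {value: 12.38, low: 9.30, high: 15.48, dist: gamma}
  rmtac_followup_q: {value: 2.23, low: 1.91, high: 2.54, dist: gamma}
  rmtac_followup_biannual: {value: 1.11, low: 0.96, high: 1.27, dist: gamma}

# Background mortality: synthetic Makeham life table calibrated so that the
# discrete monthly life expectancy at the start age matches the national value.
life_table:
  mode: makeham_calibrated
  calibrate_age: 50
  target_life_expectancy: 27.8

# In-hospital asthma case fatality: shipped synthetic fixture (the source's
# age-stratified values are not published).
case_fatality: default
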