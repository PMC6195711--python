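# SYNTHETIC in-hospital asthma case-fatality fixture.
# Monthly probability of asthma death from the hospitalized-exacerbation state,
# by age band. These are non-evidentiary stand-in constants (the age-stratified
# source values are not published); real analyses must supply their own table.
# Magnitudes are chosen so that the implied per-admission fatality matches the
# ~0.5% (rising with age) reported for asthma hospitalizations, keeping cohort
# life years close to the background life expectancy.
bands:
  - {age_low: 50, age_high: 59, q_monthly: 0.0008}
  - {age_low: 60, age_high: 69, q_monthly: 0.0013}
  - {age_low: 70, age_high: 79, q_monthly: 0.0020}
  - {age_low: 80, age_high: 89, q_monthly: 0.0040}
  - {age_low: 90, age_high: 105, q_monthly: 0.0060}
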