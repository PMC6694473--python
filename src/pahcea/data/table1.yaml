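# Canonical parameterization of the PAH cost-utility model.
# Probabilities are per 3-month cycle; costs are USD per cycle unless noted.
# horizon_cycles is the calibrated lifetime horizon (see docs/methods.md).
transitions:
  fc1_to_fc2: {mean: 0.127, se: 0.044, family: beta}
  fc2_to_fc1: {mean: 0.125, se: 0.033, family: beta}
  fc2_to_fc3: {mean: 0.127, se: 0.044, family: beta}
  fc3_to_fc2: {mean: 0.125, se: 0.033, family: beta}
  fc3_to_fc4: {mean: 0.094, se: 0.029, family: beta}
  fc4_to_fc3: {mean: 0.025, se: 0.023, family: beta}
deaths:
  fc1: {mean: 0.002, se: 0.009, family: beta}
  fc2: {mean: 0.013, se: 0.009, family: beta}
  fc3: {mean: 0.016, se: 0.011, family: beta}
  fc4: {mean: 0.240, se: 0.065, family: beta}
effects:
  sildenafil:
    rr_worsening: {mean: 0.43, se: 0.380, family: lognormal}
    rr_improvement: {mean: 4.23, se: 2.043, family: lognormal}
  beraprost:
    rr_worsening: {mean: 0.10, se: 0.199, family: lognormal}
    rr_improvement: {mean: 0.93, se: 0.612, family: lognormal}
costs:
  admissions_per_cycle:
    fc1: {mean: 0.24, se: 0.03, family: gamma}
    fc2: {mean: 0.33, se: 0.13, family: gamma}
    fc3: {mean: 0.20, se: 0.07, family: gamma}
    fc4: {mean: 0.50, se: 0.50, family: gamma}
  visits_per_cycle:
    fc1: {mean: 5.89, se: 0.48, family: gamma}
    fc2: {mean: 4.89, se: 0.47, family: gamma}
    fc3: {mean: 3.00, se: 0.47, family: gamma}
    fc4: {mean: 0.0, se: 0.0, family: fixed}
  cost_per_admission: {mean: 808.0, se: 143.0, family: gamma}
  cost_per_visit: {mean: 21.0, se: 2.0, family: gamma}
  nonmedical_per_cycle:
    fc1: {mean: 136.0, se: 27.0, family: gamma}
    fc2: {mean: 110.0, se: 24.0, family: gamma}
    fc3: {mean: 158.0, se: 64.0, family: gamma}
    fc4: {mean: 364.0, se: 364.0, family: gamma}
  drug_cost_per_cycle:
    sildenafil: 92.0
    beraprost: 88.0
  tablet_price:
    sildenafil_generic: 0.34
    sildenafil_originator: 2.18
    beraprost: 0.33
  tablets_per_cycle: 270
utilities:
  fc1: {mean: 0.74, se: 0.04, family: beta}
  fc2: {mean: 0.71, se: 0.04, family: beta}
  fc3: {mean: 0.56, se: 0.03, family: beta}
  fc4: {mean: 0.51, se: 0.04, family: beta}
settings:
  annual_discount_rate: 0.03
  cycle_length_years: 0.25
  horizon_cycles: 140
  wtp_per_qaly: 3109.0
  perspective: societal
  half_cycle_correction: false
  idr_per_usd: 13830.0
epidemiology:
  prevalence: 8000.0
  annual_incidence: 605.0
  fc2_fraction: 0.5
  fc3_fraction: 0.5
  include_year1_incidence: true
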