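# fixture-hk2009: default parameter set for the CRC screening model.
#
# Values tagged "paper" in source_tags are taken from the published Hong
# Kong cost-effectiveness study this model follows (compliance rates,
# discount rate, exchange rate, strategy definitions, utility scenario
# sets, the normal-epithelium utility anchor).  Values tagged
# "placeholder" stand in for the study's supplementary parameter tables,
# which are not publicly printed; they are literature-plausible but NOT
# calibrated, and runs on this fixture do not reproduce the published
# base-case outcome tables.  Costs are USD at 2009 prices.

natural_history:
  p_normal_to_low: 0.016
  p_low_to_high: 0.020
  p_high_to_crc: 0.050
  p_stage_progress: [0.35, 0.35, 0.40]      # undiagnosed I->II, II->III, III->IV
  p_symptomatic: [0.18, 0.34, 0.62, 0.90]   # stages I..IV
  m_crc: [0.010, 0.050, 0.140, 0.450]       # annual CRC mortality, stages I..IV
  initial_distribution: [0.85, 0.12, 0.03]  # normal / low-risk / high-risk at age 50
  crc_entry_distribution: [1.0, 0.0, 0.0]   # incident CRC enters undiagnosed stage I

# Quinquennial all-cause and CRC mortality by sex (annual probabilities).
mortality:
  - {sex: male,   age_lo: 50, age_hi: 54, all_cause: 0.0030, crc: 0.00020}
  - {sex: male,   age_lo: 55, age_hi: 59, all_cause: 0.0047, crc: 0.00030}
  - {sex: male,   age_lo: 60, age_hi: 64, all_cause: 0.0076, crc: 0.00050}
  - {sex: male,   age_lo: 65, age_hi: 69, all_cause: 0.0124, crc: 0.00070}
  - {sex: male,   age_lo: 70, age_hi: 74, all_cause: 0.0205, crc: 0.00090}
  - {sex: male,   age_lo: 75, age_hi: 79, all_cause: 0.0335, crc: 0.00120}
  - {sex: female, age_lo: 50, age_hi: 54, all_cause: 0.0017, crc: 0.00012}
  - {sex: female, age_lo: 55, age_hi: 59, all_cause: 0.0026, crc: 0.00018}
  - {sex: female, age_lo: 60, age_hi: 64, all_cause: 0.0041, crc: 0.00028}
  - {sex: female, age_lo: 65, age_hi: 69, all_cause: 0.0069, crc: 0.00040}
  - {sex: female, age_lo: 70, age_hi: 74, all_cause: 0.0120, crc: 0.00055}
  - {sex: female, age_lo: 75, age_hi: 79, all_cause: 0.0217, crc: 0.00075}

tests:
  g_fobt:
    sens_low_polyp: 0.05
    sens_high_polyp: 0.12
    sens_crc: [0.50, 0.50, 0.50, 0.50]
    specificity: 0.92
  i_fobt:
    sens_low_polyp: 0.10
    sens_high_polyp: 0.25
    sens_crc: [0.75, 0.75, 0.75, 0.75]
    specificity: 0.95
  colonoscopy:
    sens_low_polyp: 1.0
    sens_high_polyp: 1.0
    sens_crc: [1.0, 1.0, 1.0, 1.0]
    specificity: 1.0
    p_bleed: 0.0025
    p_perforation: 0.0010
    m_bleed: 0.003
    m_perforation: 0.050

compliance:
  c_screen: 0.60
  c_followup: 0.80
  c_symptomatic: 1.0

costs:
  unit_cost:
    g_fobt: 4.0
    i_fobt: 8.0
    colonoscopy: 825.0
    polypectomy: 200.0
    complication_bleed: 1500.0
    complication_perforation: 5000.0
    specialist_visit: 115.0
  initial_cost: [20000.0, 28000.0, 35000.0, 42000.0]     # first year, stages I..IV
  continuing_cost: [1000.0, 1500.0, 2500.0, 12000.0]     # each later year (terminal = continuing)
  hkd_per_usd: 7.8

utilities:
  u_normal: 1.0
  u_low_polyp: 0.95
  u_high_polyp: 0.93
  u_undiag: [0.87, 0.85, 0.80, 0.70]
  u_diag: [0.87, 0.85, 0.80, 0.70]

econ:
  discount_rate: 0.035
  horizon_years: 25
  cycle_length: 1
  cohort_size: 100000
  entry_age: 50
  exit_age: 75
  wtp_threshold: 50000.0
  half_cycle_correction: true
  sex_weights: [0.5, 0.5]

strategies:
  - {name: no_screening,    primary_test: null,        interval_years: null, start_age: 50, stop_age: 75}
  - {name: annual_gfobt,    primary_test: g_fobt,      interval_years: 1,    start_age: 50, stop_age: 75}
  - {name: biennial_gfobt,  primary_test: g_fobt,      interval_years: 2,    start_age: 50, stop_age: 75}
  - {name: annual_ifobt,    primary_test: i_fobt,      interval_years: 1,    start_age: 50, stop_age: 75}
  - {name: biennial_ifobt,  primary_test: i_fobt,      interval_years: 2,    start_age: 50, stop_age: 75}
  - {name: colonoscopy_10y, primary_test: colonoscopy, interval_years: 10,   start_age: 50, stop_age: 75}

source_tags:
  natural_history.p_normal_to_low: placeholder
  natural_history.p_low_to_high: placeholder
  natural_history.p_high_to_crc: placeholder
  natural_history.p_stage_progress: placeholder
  natural_history.p_symptomatic: placeholder
  natural_history.m_crc: placeholder
  natural_history.initial_distribution: placeholder
  natural_history.crc_entry_distribution: placeholder
  mortality: placeholder
  tests.g_fobt: placeholder
  tests.i_fobt: placeholder
  tests.colonoscopy.specificity: paper
  tests.colonoscopy.sens_crc: paper
  tests.colonoscopy.p_bleed: placeholder
  tests.colonoscopy.p_perforation: placeholder
  tests.colonoscopy.m_bleed: placeholder
  tests.colonoscopy.m_perforation: placeholder
  compliance.c_screen: paper
  compliance.c_followup: paper
  compliance.c_symptomatic: paper
  costs.unit_cost: placeholder
  costs.initial_cost: placeholder
  costs.continuing_cost: placeholder
  costs.hkd_per_usd: paper
  utilities.u_normal: paper
  utilities.u_low_polyp: placeholder
  utilities.u_high_polyp: placeholder
  utilities.u_undiag: placeholder
  utilities.u_diag: placeholder
  econ.discount_rate: paper
  econ.horizon_years: paper
  econ.cohort_size: paper
  econ.entry_age: paper
  econ.exit_age: paper
  econ.wtp_threshold: paper
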