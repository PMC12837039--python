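# Literature and program constants for the Bulgarian 2024 pilot colorectal-cancer
# (CRC) screening evaluation. One entry per published value; comments name the
# original data source. All monetary amounts are EUR unless suffixed _bgn
# (fixed currency-board peg: 1.95583 BGN per EUR).
version: 1

survival:
  # SEER 5-year survival by pooled stage group
  five_year_survival_stage_i_ii: 0.91
  five_year_survival_stage_iii_iv: 0.45

recurrence:
  # Danish registry 5-year cumulative incidence of recurrence, by site and stage
  cif_colon_stage1: 0.068
  cif_rectal_stage1: 0.095
  cif_colon_stage2: 0.116
  cif_rectal_stage2: 0.184

stage_split:
  # Dutch screening-programme stage distribution at diagnosis
  with_screening: {early: 0.67, late: 0.33}
  without_screening: {early: 0.46, late: 0.54}

utilities:
  # Mean health-state utilities pooled over stage pairs (Ness et al. 1999)
  stage_i_ii: 0.74
  stage_iii_iv: 0.46
  dead: 0.0

costs_eur:
  screening_per_participant: 7.84      # programme budget / participants
  colonoscopy: 498.08                  # NHIF tariff, with/without polypectomy or resection
  late_stage_treatment: 6417.85        # NHIF, 6-month stage III-IV course (medicines + administration)
  late_stage_medicines: 2031.53
  late_stage_administration: 4383.33
  palliative_care: 1076.78

model:
  horizon_cycles: 50                   # lifetime horizon, annual cycles
  cycle_length_years: 1.0
  discount_rate: 0.035                 # applied to costs and utilities after the first year

psa:
  iterations: 1000
  wtp_eur: 44081.03                    # 3x Bulgarian GDP per capita (BGN 86,215)
  cost_sd_fraction: 0.20               # normal
  utility_sd_fraction: 0.20            # gamma
  probability_sd_fraction: 0.10        # beta

detected_cohort:
  # Slovenian FIT programme detection rate applied to the Bulgarian positives
  fit_positive_for_cua: 13263          # CUA-section count (= age-strata sum); the campaign table header prints 13,281
  reference_detected: 862
  reference_positive: 15310

projection:
  base_year: 2024
  base_population_50_74: 2233977       # NSI, ages 50-74
  annual_population_decline: 0.01147   # NSI
  crc_incidence_per_1000: 0.431        # pooled male+female incidence
  n_years: 5

gdp:
  gdp_total_eur: 93946530472.80        # NSI, 2023
  gdp_total_bgn: 183743400000.00
  working_age_population: 3900300
  working_share_of_patients: 0.56

campaign:
  total_tests: 93381                   # tests treated as participants
  original_target: 50000
  n_positive_total: 13281
  n_suspicious: 25
  sex:
    female: {tested: 59092, positive: 7047}
    male: {tested: 34219, positive: 6225}
    unspecified: {tested: 70, positive: 9}
  age:
    "18-49": {tested: 15121, positive: 1280}
    "50-60": {tested: 26163, positive: 3081}
    "61-74": {tested: 39061, positive: 6299}
    "75+": {tested: 12873, positive: 2603}
  channels:
    television: 41192
    personal_network: 22443
    laboratory: 7417
    physician: 5989
    other: 13143
  budget_total_eur: 731340.27
  budget_shares: {logistics: 0.46, communication: 0.34, professional: 0.05, admin: 0.15}

published_results:
  # Base-case outputs of the original TreeAge build; used only as calibration
  # targets and reference points, never as computed outputs of this package.
  per_patient:
    cost_with: 1137.24
    qaly_with: 8.46
    cost_without: 1204.31
    qaly_without: 6.88
    delta_cost: -67.07
    delta_qaly: 1.58
  detected_cohort_totals:
    n_detected: 747
    cost_with: 849515.95
    qaly_with: 6317.43
    cost_without: 899617.56
    qaly_without: 5137.84
    delta_cost: -50101.61
    delta_qaly: 1179.59
  psa:
    mean_cost_with: 1139.72
    mean_qaly_with: 8.51
    mean_cost_without: 1205.68
    mean_qaly_without: 6.93
    mean_delta_cost: -65.95
    mean_delta_qaly: 1.59
    acceptability: 0.991
  gdp_contribution_eur: 15947405.22
  working_age_qalys: 662.08
  budget_projection:
    population: [2233977, 2208353, 2183023, 2157984, 2133232]
    new_cases: [963, 952, 941, 930, 919]
    late_without: [520, 514, 508, 502, 496]
    late_with: [318, 314, 310, 307, 303]
    avoided: [202, 200, 198, 195, 193]
    avoided_total: 988
    savings_eur: [1297671.85, 1282390.15, 1268073.98, 1253529.17, 1239151.19]
    savings_total_eur: 6341213.73
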