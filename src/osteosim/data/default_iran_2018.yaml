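# default_iran_2018: base-case parameter set (Iranian health-system
# perspective, 2018 governmental tariffs, currency integer IRR).
# The background mortality table and baseline utility curve are SYNTHETIC
# stand-ins (see docs/methods.md); everything else reproduces the published
# input tables.
meta:
  name: default_iran_2018
  currency: IRR
  usd_exchange_rate: 42000

incidence:   # annual fractures per 1000 women
  bands: [[50, 54], [55, 59], [60, 64], [65, 69], [70, 74], [75, 79], [80, 84], [85, null]]
  per_1000:
    hip:                [0.39, 0.65, 1.57, 2.53, 4.70, 9.07, 15.02, 24.60]
    wrist:              [4.18, 4.56, 5.68, 6.91, 9.04, 10.33, 12.08, 13.23]
    vertebral:          [1.61, 1.58, 2.73, 3.98, 7.39, 11.11, 11.07, 14.10]
    other_nonvertebral: [1.39, 2.25, 1.67, 2.47, 5.08, 8.39, 15.18, 27.84]

mortality_rr:   # relative risk of death after fracture, women
  bands: [[70, 74], [75, 79], [80, 84], [85, 89], [90, 94]]
  first_year:
    hip:       [5.91, 4.46, 3.37, 2.55, 1.93]
    vertebral: [6.47, 4.63, 3.31, 2.37, 1.69]
    other:     [4.06, 2.94, 2.12, 1.53, 1.11]
  subsequent:
    hip:       [4.55, 3.42, 2.57, 1.94, 1.46]
    vertebral: [4.23, 3.01, 2.14, 1.53, 1.09]

utilities:   # multipliers on age-specific baseline utility
  first_year:
    hip: 0.792
    vertebral: 0.626
    wrist: 0.977
    # not printed for the first year; midpoint of the PSA range 0.84-0.90
    other_nonvertebral: 0.87
  subsequent_years:
    hip: 0.9
    vertebral: 0.93

treatment:   # 20 ug daily teriparatide, 18-month course
  rr:
    hip: 0.50
    vertebral: 0.35
    wrist: 0.54
    other_nonvertebral: 0.47
  duration_months: 18
  offset_months_vertebral: 24
  offset_months_nonvertebral: 30
  annual_persistence: 0.703

costs:   # integer IRR, governmental tariff
  acute_package:
    hip: 150000000
    vertebral: 100000000
    wrist: 80000000
    other_nonvertebral: 80000000
  one_off_items:
    wheelchair_or_walking_aid: {amount: 10000000, trigger: hip}
    waving_bed: {amount: 10000000, trigger: hip}
  recurring_items:
    nursing_at_home:
      amount: 60000000           # 6-month total, first post-fracture cycle
      rule: first_post_fracture_cycle
      sites: [hip, vertebral]
    physiotherapy:
      amount: 10500000           # once in the first year after fracture
      rule: first_year_once
      sites: [hip, vertebral]
    bed_sore_management:
      amount: 4000000            # per 6 months while in an acute state
      rule: per_acute_cycle
      sites: [hip, vertebral]
    bmd_test:
      amount: 1400000            # annual bone-mineral-density test
      rule: every_second_cycle
    calcium_vitd_naproxen:
      amount: 1300000            # both arms, every cycle
      rule: per_cycle
  drug_cost_per_pen: 4400000     # CinnoPar 600 mcg pen, 30 dose-days
  pen_dose_days: 30

econ:
  discount_rate_costs: 0.072
  discount_rate_effects: 0.05
  cycle_years: 0.5
  max_age: 100
  gdp_per_capita: 138000000      # IRR, 2017 fiscal year
  # wtp_grid omitted: defaults to 0..3*GDP/capita in steps of GDP/20

history:
  # Same-site re-fracture elevation, years 1..5 after a fracture; the source
  # model cites this effect without printing values -- placeholder schedule.
  schedule: [2.0, 1.5, 1.3, 1.2, 1.1]

background:
  # SYNTHETIC female life table: Gompertz hazard h(x) = b*exp(c*x), with b
  # calibrated so remaining life expectancy at age 70 is 14.0 years.
  gompertz:
    makeham_a: 0.0
    gompertz_b: 3.269056424811087e-05
    gompertz_c: 0.095
  # SYNTHETIC baseline utility: 0.86 at age 50, -0.004/year, floor 0.4.
  utility_curve:
    anchor_age: 50
    anchor_utility: 0.86
    slope_per_year: 0.004
    floor: 0.4

simulation:
  start_age: 70.0
  prevalent_vertebral_fraction: 0.0
  max_expanded_states: 200000

psa:
  records:
    - {name: start_age, family: normal, lower: 60, upper: 80,
       target: start_age, truncate: [55, 90]}
    - {name: hip_surgery_cost, family: gamma, lower: 28000000, upper: 55000000,
       target: surgery.hip}
    - {name: other_surgery_cost, family: gamma, lower: 14000000, upper: 26000000,
       target: surgery.other_nonvertebral}
    - {name: vertebral_surgery_cost, family: gamma, lower: 37000000, upper: 67000000,
       target: surgery.vertebral}
    - {name: wrist_surgery_cost, family: gamma, lower: 14000000, upper: 26000000,
       target: surgery.wrist}
    - {name: rr_hip, family: lognormal, lower: 0.09, upper: 2.73, point: 0.50,
       target: treatment.rr.hip}
    - {name: rr_other, family: lognormal, lower: 0.25, upper: 0.88, point: 0.47,
       target: treatment.rr.other_nonvertebral}
    - {name: rr_vertebral, family: lognormal, lower: 0.22, upper: 0.55, point: 0.35,
       target: treatment.rr.vertebral}
    - {name: rr_wrist, family: lognormal, lower: 0.22, upper: 1.35, point: 0.54,
       target: treatment.rr.wrist}
    - {name: utility_hip_y1, family: beta, lower: 0.66, upper: 0.72,
       target: utilities.first_year.hip}
    - {name: utility_hip_y2, family: beta, lower: 0.76, upper: 0.83,
       target: utilities.subsequent_years.hip}
    - {name: utility_other, family: beta, lower: 0.84, upper: 0.90,
       target: utilities.first_year.other_nonvertebral}
    - {name: utility_vertebral_y1, family: beta, lower: 0.53, upper: 0.64,
       target: utilities.first_year.vertebral}
    - {name: utility_vertebral_y2, family: beta, lower: 0.88, upper: 0.97,
       target: utilities.subsequent_years.vertebral}
    - {name: utility_wrist, family: beta, lower: 0.87, upper: 0.92,
       target: utilities.first_year.wrist}
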