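# Default parameters: the 2013/14 cross-sectional survey of anaesthetists in the
# French- and Italian-speaking cantons of Switzerland, plus the default policy
# scenario (constant foreign-trainee quota with a strict return policy).
schema: quotasim-params-v1

survey:
  listed_n: 506
  responded_n: 416
  age_band_counts:
    "<=35": 97
    "36-55": 254
    ">=56": 56
  gender_counts:
    female: 171
    male: 239
  parttime_counts:
    part_time: 97
    full_time: 315
  nationality_counts:
    swiss: 338
    european: 69
    other: 6
  position_by_nationality:
    swiss:
      fixed: 218
      transition: 80
      training: 42
    foreign:
      fixed: 31
      transition: 20
      training: 24
  hospital_by_nationality:
    swiss:
      university: 133
      district: 119
      private: 82
      office: 2
    foreign:
      university: 28
      district: 36
      private: 10
      office: 0
  retirement_age:
    male: {mean: 62.0, sd: 3.1}
    female: {mean: 60.0, sd: 2.8}
  # Years between medical graduation and specialty certification (FMH title).
  training_duration_counts:
    5: 10
    6: 32
    7: 42
    8: 36
    9: 31
    10: 36
    11: 24
    12: 15
    13: 10
    14: 7
    "15+": 25

# Survey headcounts by position, used to initialise the simulation.
state_counts:
  TRAINING: 66
  TRANSITION: 99
  FIXED: 248

scenario:
  start_year: 2014
  horizon_year: 2024
  quota: 66
  fixed_capacity: 244
  transition_demand: null          # null -> end-of-start-year transition headcount
  training_state_years: 5
  return_policy: true
  foreign_departure_hazard: null   # null -> calibrate (see `calibration`)
  legal_retirement_age:
    male: 65.0
    female: 64.0

fte:
  anchor_gap_percent: 10.0         # unfilled FTE share of transition posts at end of the baseline year
  part_time_weight: null           # null -> solve from the anchor

calibration:
  anchors:
    2014: 93
    2024: 58
  hazard_grid: {lo: 0.0, hi: 0.5, step: 0.01}
  replicates_per_point: 200

# Scattered published figures used by `quotasim describe`.
printed_figures:
  swiss_medical_graduates:
    year_before: 2000
    year_after: 2010
    graduates_before: 756
    graduates_after: 813
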