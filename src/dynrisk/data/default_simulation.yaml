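n_participants: 15565
schedule_mix:
  1: 0.15
  2: 0.4
  3: 0.3
  4: 0.15
factor_means:
  sbp: 121.0
  dbp: 74.8
  tc: 207.0
  hdl: 51.6
factor_sds:
  sbp: 17.0
  dbp: 10.5
  tc: 40.0
  hdl: 15.5
slope_sds:
  sbp: 1.2
  dbp: 0.7
  tc: 2.0
  hdl: 0.6
noise_sds:
  sbp: 6.0
  dbp: 4.0
  tc: 10.0
  hdl: 4.0
factor_correlation:
- - 1.0
  - 0.6
  - 0.15
  - -0.1
- - 0.6
  - 1.0
  - 0.15
  - -0.05
- - 0.15
  - 0.15
  - 1.0
  - 0.1
- - -0.1
  - -0.05
  - 0.1
  - 1.0
hazard_coefs:
  last:
    sbp: 0.015
    dbp: 0.0
    tc: 0.004
    hdl: -0.02
  slope:
    sbp: 0.1
    dbp: 0.0
    tc: 0.02
    hdl: 0.0
  static:
    age: 0.07
    male: 0.4
    black: 0.05
    smoker: 0.45
    diabetes: 0.7
    htn_treatment: 0.25
baseline_hazard: 0.0081
censoring_rate: 0.02
horizon: 10.0
age_mean: 50.2
age_sd: 7.2
age_center: 50.0
age_bounds:
- 40.5
- 74.5
p_female: 0.548
p_black: 0.27
p_smoker: 0.297
p_diabetes: 0.091
p_htn_treatment: 0.239
p_prior_ascvd: 0.0
missing_rate: 0.03
observation_window: 8.0
seed: 0
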