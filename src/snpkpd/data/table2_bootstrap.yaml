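# Bootstrap-average column of the published population K-PD estimates.
# This is the default parameter set for the dose-finding simulations: it
# reproduces the published dosing tables, which the final-model column
# does not for the low-EC50 subpopulation.
schema: snpkpd-params/1
theta:
  cl_L_per_h_per_70kg: 3.13
  v_L_per_70kg: 1.0
  s0_mmHg: 76.0
  pwr_age: 0.032
  median_age_y: 11.33
  emax_mmHg: 21.9
  ec50_low_ug_per_L: 104.3
  ec50_high_ug_per_L: 458.0
  gamma: 7.27
  slope_mmHg_per_h: 11.0
  p_high: 0.701
omega:
  v: 0.82
  cl: 0.627
  s0: 0.132
  ec50_low: 0.221
  ec50_high: 0.108
  emax: 0.765
  slope: 2.11
sigma:
  prop: 0.329
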