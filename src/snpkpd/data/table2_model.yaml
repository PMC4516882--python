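# Final-model column of the published population K-PD estimates.
# The age power uses the published covariate-equation value (0.0338);
# the model column alone prints 0.0333.
schema: snpkpd-params/1
theta:
  cl_L_per_h_per_70kg: 3.12
  v_L_per_70kg: 1.0
  s0_mmHg: 76.0
  pwr_age: 0.0338
  median_age_y: 11.33
  emax_mmHg: 22.65
  ec50_low_ug_per_L: 138.0
  ec50_high_ug_per_L: 460.0
  gamma: 7.23
  slope_mmHg_per_h: 12.3
  p_high: 0.699
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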