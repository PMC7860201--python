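name: xy_cr0
initial_system: XY
cr_init_freq: 0.0
cr_inheritance: CR_dominant
cn_value: 0.9
libido: 3
climate:
  b_sig: 0.003
  sd_between: 0.01
  sd_within: 0.05
  burn_in_years: 50
  m0: 0.0
life:
  maturation_age: 2
  adult_annual_survival: 0.5
  juvenile_annual_survival: 0.5
  max_age: 8
  fert_f: 40.0
  Nmax: 400
  n_start_adults: 200
  ww_viability: 1.0
genetics:
  sig_a: 1.0
  z_low: 2.4
  thr_model: biallelic
max_warming_years: 600
seed: null
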