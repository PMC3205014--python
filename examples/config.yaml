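# Run configuration for `polarperf simulate`.
# generator: parameters of the synthetic NC/AC cohort model
# cohort: subjects per (gender, BMI) stratum; defaults mirror the study strata
seed: 1

generator:
  base_level: 100.0
  nc_effect_male_inferior: 0.14
  nc_effect_female_anterior: 0.06
  nc_effect_female_lateral: 0.04
  obesity_multiplier: 1.5
  ac_residual: 0.1
  subject_sd: 0.10
  pixel_noise_sd: 6.0
  noise_smooth_sigma: 1.5

cohort:
  n_male_normal: 102
  n_male_obese: 24
  n_female_normal: 165
  n_female_obese: 40
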