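# Full-scale demo: synthetic two-wave panel resembling the motivating
# cohort (13 nodes, n = 1816, 29.2% missing observations under MAR),
# imputed with 10 chains and analysed end to end.
seed: 1
out_dir: clpnet_demo_run
simulation:
  n: 1816
  n_symptom: 5
  n_cognition: 4
  n_covariate: 4
  density: 0.2
  effect_range: [0.1, 0.3]
  cross_density: 0.05
  missing_rate: 0.292
  missing_mechanism: MAR
imputation:
  m: 10
  n_iter: 20
estimation:
  gamma: 0.5
  n_lambda: 100
  lambda_min_ratio: 0.01
  correlation_method: pearson
stability:
  n_boot_ci: 1000
  n_boot_cs: 250
  drop_grid: [0.05, 0.1, 0.15, 0.2, 0.25, 0.3, 0.35, 0.4,
              0.45, 0.5, 0.55, 0.6, 0.65, 0.7, 0.75]
pool: cells
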