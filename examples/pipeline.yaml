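# End-to-end run on a synthetic cohort, scaled for a quick demonstration.
# Usage: mirsel run-all --config examples/pipeline.yaml
out_dir: scratch/demo_run
simulation:
  n_per_subtype: [40, 25, 15, 25, 25]
  n_features: 80
  informative_per_subtype: 4
  n_multisubtype_features: 6
  effect_size: 2.0
  noise_sd: 2.0
  n_prognostic: 3
  prognostic_beta: 1.0
  seed: 7
penalty:
  alpha_grid: [0.2, 0.4, 0.8]
  lambda_path_length: 8
  cv_folds: 3
  convergence_tol: 1.0e-6
  lambda_min_ratio: 1.0e-3
M: 10
n_repeats: 3
min_subtypes: 3
coef_thresh: 0.2
p_thresh: 0.05
seed: 1
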