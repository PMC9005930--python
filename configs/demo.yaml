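output_dir: seedmenus_demo
stack_path: null
occurrences_path: null
traits_path: null
sites_path: null
master_seed: 1
lifespans: {}
simulate:
  nrows: 64
  ncols: 64
  cell_km: 1.0
  n_covariates: 8
  autocorrelation_range: 4.0
  n_species: 3
  n_occurrences: 300
  intercept: -8.0
  beta_low: 2.0
  beta_high: 3.0
  n_causal: 2
  access_bias_strength: 0.0
  n_roads: 3
model_space:
  max_terms: 4
  r_cut: 0.7
  spec_cap: 24
cv:
  n_runs: 10
  holdout: 0.2
  thin_block_km: 10.0
  thin_max_per_block: 3
fit:
  n_trees: 200
  maxent_regularization: 1.0
  gam_nbasis: 10
  min_presences: 20
  families:
  - smooth_additive
  - tree_ensemble
  - maxent_like
ensemble:
  n_keep: 5
  se_mode: se
threshold:
  kind: fixed
  fixed_value: 0.4
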