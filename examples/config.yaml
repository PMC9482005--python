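# Synthetic end-to-end configuration: a virtual species whose native and
# introduced samples are drawn from the same windowed Gaussian niche.
seed: 5

simulate:
  nrows: 64
  ncols: 64
  n_layers: 5
  collinear_groups: [[1, 2]]
  niche_center: [0.0, 0.0]
  niche_cov: [[0.25, 0.0], [0.0, 0.25]]
  native_window: {xmin: -1.0, xmax: 1.0, ymin: -1.0, ymax: 1.0}
  introduced_window: {xmin: -1.0, xmax: 1.0, ymin: -1.0, ymax: 1.0}
  n_native: 250
  n_introduced: 500

rarefaction:
  radius_km: 5.0

collinearity:
  r_threshold: 0.70

niche:
  grid_resolution: 100
  bandwidth_rule: silverman
  mass_quantile: 0.95

sdm:
  learners: [logit, envelope]
  n_pa_sets: 2
  repeats: 2
  train_fraction: 0.7
  tss_retain: 0.7
  auc_retain: 0.8
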