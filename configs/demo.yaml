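# Demo configuration: a scaled-down synthetic study that runs end-to-end
# in under a minute. One planted effect-cluster pair, 10 controls and
# 14 treated subjects on a 14-voxel grid; permutation inference reduced to
# 20 rounds so the demo stays fast.
seed: 7
cohort:
  n_group_a: 10
  n_group_b: 14
  grid_shape: [14, 14, 14]
  n_frames: 200
  n_effect_clusters: 1
  hub_radius_vox: 1.6
  effect_size_d: 2.5
  treatment_signal_r: 0.7
features:
  min_extent: 4
models:
  c_grid: [1.0, 10.0]
  gamma_grid: [0.05, 0.5]
  inner_cv_folds: 3
  n_perm: 20
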