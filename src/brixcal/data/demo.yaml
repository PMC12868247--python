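# Demo experiment: the default synthetic study conditions.
# 100 samples on the 486-band fused VL+NIR grid, seed-42 9:1 split,
# fixed full-band hyperparameters and searched characteristic-band ones.
synthetic:
  n_samples: 100
  seed: 42
split_seed: 42
train_fraction: 0.9
plsr_components: 10
lasso_alpha: 0.001
ridge_alpha: 0.001
spa_size_range: [3, 10]
cap_fraction: 0.10
gap_tolerance_nm: 15.0
validation_seed: 7
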