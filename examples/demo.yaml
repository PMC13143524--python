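data:
  manifest: runs/demo-data/manifest.csv
model:
  variant: csfnet
  backbone: tiny
  feature_dim: 64
  image_size: 64
train:
  epochs_max: 15
  batch_size: 16
eval:
  k_folds: 2
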