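# Desk-scale profile: minutes on one CPU, same pipeline end to end.
simulator:
  records_per_cell: 4
  duration_s: 60.0
model:
  epochs: 20
  n_categories: 8
  latent_dim: 16
  hidden_cat: [64]
  hidden_en: [128, 64]
  hidden_de: [64, 128]
  val_interval_epochs: 5
  k_val: 8
  max_train_windows: 3000
  max_val_windows: 512
detector:
  k_infer: 8
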