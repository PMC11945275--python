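# Reference experimental settings: full-scale training.
signals:
  window_seconds: 10.0
model:
  epochs: 2000
  lr0: 0.0004
  lr_decay: 0.95
  lr_step_epochs: 50
  anneal_period_epochs: 200
  val_interval_epochs: 20
  k_val: 32
detector:
  contamination: 0.01
  k_infer: 32
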