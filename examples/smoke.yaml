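# Desk-scale end-to-end run: 8 synthetic subjects, scaled-down model.
seed: 3
simulate:
  n_subjects: 8
  duration_s: 120.0
  hr_min: 50.0
  hr_max: 100.0
preprocess:
  window_s: 4.0
  stride_s: 1.0
  hr_min: 35.0
  hr_max: 120.0
model:
  filters_per_kernel: 8
  tcn_channels: 32
  lstm_hidden: 32
  pool_size: 4
  max_epochs: 20
  batch_size: 32
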