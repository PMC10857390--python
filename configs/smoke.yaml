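# Minimal end-to-end pipeline check (< 1 minute):
#   gaitforce run-all --config configs/smoke.yaml --out scratch/smoke
design:
  n_young: 2
  n_elderly: 2
  cycles_per_subject_per_speed: 2
  speeds: [1.5]
  train_cycles_per_subject: 1
  n_samples: 100
  seed: 0
models: [cnn_lstm]
train:
  epochs: 5
  batch_size: 8
  seed: 0
  dtype: float32
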