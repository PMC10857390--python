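# Fused-speed protocol: 1200 cycles across 1.2/1.5/1.8 m/s,
# 960 train / 240 validation via the per-subject 8/2 split per speed.
# Several hours on one CPU at this scale.
design:
  n_young: 20
  n_elderly: 20
  cycles_per_subject_per_speed: 10
  speeds: [1.2, 1.5, 1.8]
  train_cycles_per_subject: 8
  n_samples: 100
  seed: 0
models: [cnn, lstm, cnn_lstm]
train:
  epochs: 200
  batch_size: 32
  seed: 0
  dtype: float32
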