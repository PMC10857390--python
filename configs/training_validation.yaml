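# Per-speed training/validation protocol at full scale: 40 subjects,
# 10 cycles per subject per speed (400 cycles/speed, 320/80 split).
# One model trained across the listed speeds; run one config per speed
# for the per-speed variant.  Several hours on one CPU at this scale —
# shrink the design for exploratory runs.
design:
  n_young: 20
  n_elderly: 20
  cycles_per_subject_per_speed: 10
  speeds: [1.2]
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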