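# Full pipeline configuration. Every field shown here has the same
# default inside the package; edit what you need and run
#   vo2lstm run-all --config examples/config.yaml --out runs/demo
master_seed: 42
output_dir: runs/demo
stages: [simulate, preprocess, features, train, evaluate]

simulation:
  walk_speeds: [1.3, 1.8]        # m/s
  run_speeds: [2.5, 3.5]         # m/s
  stage_duration: 180.0          # s per speed stage
  rest_duration: 120.0           # s of standing rest between stages
  motion_sample_rate: 100.0      # Hz
  vo2_rate: 0.2                  # Hz (one breath-averaged sample every 5 s)
  hr_rate: 1.0                   # Hz
  vo2_noise_sd_abs: 125.0        # mL/min, divided by body mass
  hr_noise_sd: 2.0               # bpm
  offsets: [0.0, 2.0, -1.5]      # injected clock offsets: motion, vo2, hr (s)
  jump_time: 10.0                # s, synchronization jump

preprocess:
  sg_polyorder: 3
  sg_window: 11                  # samples (55 s at 0.2 Hz)
  sg_passes: 3
  outlier_mad_threshold: 5.0
  sync_tolerance: 0.2            # s

features:
  min_period: 0.2                # s, shortest admissible step
  min_prominence: 0.03           # m, vertical-oscillation peak prominence
  target_anchor: end             # V̇O2 target interpolated at step end

model:
  window_length: 50              # steps per input sequence
  hidden_units: 150
  lstm_layers: 1
  features: [mean_speed, speed_p2p, duration, vertical_disp_p2p]
  learning_rate: 0.005
  epochs: 300                    # 8000 for field-sized datasets
  batch_size: 64
  split_ratio: 0.8
  split_mode: shuffled           # or "blocked" (leakage-free)
  seed: 0                        # overridden by the derived stage seed
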