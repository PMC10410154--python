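# Population-coded variant used for global-local co-learning: the last
# FCLIF layer has 7 neurons per category; category scores are population
# means of time-averaged spikes.  Batchnorm keeps the deep spiking stack
# active (homeostasis).
seed: 0
network:
  mode: iim
  t_total: 20
  input_shape: [2, 20, 20]
  aggregation: mean
  blocks:
    - {kind: conv_lif, in_channels: 2, out_channels: 8, stride: [2, 2], norm: batchnorm}
    - {kind: conv_lif, in_channels: 8, out_channels: 16, stride: [2, 2], norm: batchnorm}
    - {kind: fc_lif, in_channels: 400, out_channels: 64, norm: batchnorm}
    - {kind: fc_lif, in_channels: 64, out_channels: 21}
  head: {kind: population, n_classes: 3, n_per_category: 7}
dataset:
  kind: synthetic_motion
  classes: [left, right, up]
  t_steps: 20
  hw: [20, 20]
  n_train: 200
  n_val: 60
  val_noise_ratio: 0.1
train:
  optimizer: adam
  lr: 0.001
  weight_decay: 0.0001
  epochs: 20
  batch_size: 20
plasticity:
  phases:
    - {kind: global}
    - {kind: local, rule: r_stdp, lr: 0.001, theta: 0.95, eta: 1.0, passes: 2}
output_dir: scratch/motion_population
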