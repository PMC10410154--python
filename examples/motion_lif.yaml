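# 3-class moving-bar classifier: two ConvLIF blocks, sum aggregation,
# linear head.  Classes differ only in motion direction, so the task is
# unsolvable from time-aggregated frames alone.
seed: 0
network:
  mode: iim
  t_total: 20
  input_shape: [2, 20, 20]
  aggregation: sum
  blocks:
    - {kind: conv_lif, in_channels: 2, out_channels: 8, stride: [2, 2]}
    - {kind: conv_lif, in_channels: 8, out_channels: 16, stride: [2, 2]}
  head: {kind: linear, n_classes: 3}
dataset:
  kind: synthetic_motion
  classes: [left, right, up]
  t_steps: 20
  hw: [20, 20]
  n_train: 200
  n_val: 60
train:
  optimizer: adam
  lr: 0.001
  weight_decay: 0.0001
  epochs: 15
  batch_size: 20
output_dir: scratch/motion_lif
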