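experiment: hh_prebotzinger
seed: 0
system: hh
params:
  n_neurons: 1024
plan:
  n_lc: 3
  n_test: 1
  perturb_mode: scale_factors
  factors:
  - 0.9
  - 1.1
  horizon: 20.0
  dt: 0.002
sampling_options: {}
embed:
  eps: 4000.0
  n_modes: 12
  selection: local_linear_regression
  selection_params:
    threshold: 0.5
    max_modes: 2
grid:
  n: 64
  fraction: 0.7
model:
  n_derivs: 3
  stencil_length: 5
  hidden_layers: 3
  width: 64
  activation: tanh
train:
  lr: 0.002
  batch: 128
  epochs: 400
  patience: 10
rollout:
  scheme: forward_euler
  dt: 0.002
  boundary: corridor
  corridor_width: 4
  n_keep: 10
  horizon: 2.0
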