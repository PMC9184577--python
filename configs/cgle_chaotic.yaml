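experiment: cgle_chaotic
seed: 0
system: cgle_chaotic
params:
  c1: 0.0
  c2: -3.0
  L: 80.0
  n_mesh: 256
  boundary: periodic
  dt_sample: 0.02
plan:
  n_lc: 20
  n_test: 2
  perturb_mode: scale_factors
  horizon: 20.0
  dt: 0.02
sampling_options:
  t_burn: 1000.0
  noise_sigma: 0.1
embed:
  eps: 100.0
  n_modes: 12
  selection: local_linear_regression
  selection_params:
    threshold: 0.5
    max_modes: 2
grid:
  n: 256
  periodic: true
model:
  n_derivs: 2
  stencil_length: 5
  hidden_layers: 4
  width: 96
  activation: swish
train:
  lr: 0.002
  batch: 128
  epochs: 400
  patience: 10
rollout:
  scheme: rk45
  dt: 0.02
  boundary: periodic
  n_keep: null
  horizon: 4.0
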