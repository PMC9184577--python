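experiment: sl_gamma_sweep
seed: 0
system: sl_gamma_sweep
params:
  K: 1.2
  gamma: 1.7
  omega0: 0.2
  n_osc: 512
gamma_values:
- 1.7
- 1.72
- 1.74
- 1.76
- 1.78
- 1.8
plan:
  n_lc: 20
  n_test: 5
  perturb_mode: floquet_direction
  eps_perturb: 0.1
  horizon: 200.0
  dt: 0.05
sampling_options:
  settle_time: 400.0
  monodromy_steps: 1024
embed:
  eps: 10.0
  n_modes: 12
  selection: local_linear_regression
  selection_params:
    threshold: 0.5
    max_modes: 1
grid:
  n: 128
  periodic: false
model:
  n_derivs: 3
  stencil_length: 9
  hidden_layers: 4
  width: 96
  activation: tanh
  param_input: true
train:
  lr: 0.001
  batch: 1024
  epochs: 60
  patience: 7
rollout:
  scheme: forward_euler
  dt: 0.05
  boundary: corridor
  corridor_width: 4
  n_keep: 3
  horizon: 20.0
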