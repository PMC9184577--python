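experiment: cgle_noflux
seed: 0
system: cgle_noflux
params:
  c1: 1.0
  c2: 2.0
  L: 200.0
  n_mesh: 256
  boundary: no_flux
  dt_sample: 0.001
plan:
  n_lc: 20
  n_test: 1
  perturb_mode: scale_factors
  factors:
  - 0.9
  - 1.1
  horizon: 20.0
  dt: 0.001
  d_tau: 100.0
  t_min: 2000.0
sampling_options:
  n_keep_agents: 128
embed:
  eps: median
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
train:
  lr: 0.001
  batch: 1024
  epochs: 60
  patience: 7
rollout:
  scheme: forward_euler
  dt: 0.001
  boundary: corridor
  corridor_width: 4
  n_keep: 2
  horizon: 2.0
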