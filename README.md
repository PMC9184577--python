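# empde — emergent PDEs for heterogeneous agent ensembles

Large systems of coupled, heterogeneous agents — oscillator ensembles,
neuronal networks — often have no physical space coordinate in which to
write a field equation, yet their long-term dynamics collapse onto a
low-dimensional slow manifold. `empde` discovers data-driven *emergent*
spatial coordinates for such ensembles with diffusion maps, and then learns
a partial differential equation in those coordinates:

    ∂W/∂t = f(W, ∂W/∂x̃, ∂²W/∂x̃², ∂³W/∂x̃³; γ)

where `x̃` is the learned coordinate, `f` is a small fully connected neural
network trained on finite-difference derivatives of the sampled fields, and
`γ` is an optional system parameter, letting one learned model capture
collective bifurcations. Inference integrates the learned PDE with narrow
ground-truth *boundary corridors* (analytic boundary conditions are unknown
in emergent space) and a truncated-SVD filter that keeps trajectories in
the subspace where training data existed.

The package is aimed at researchers in complex-systems modeling and
computational neuroscience who want reduced, predictive field models of
agent simulations. It ships three fully tested benchmark systems:

* the 1D complex Ginzburg-Landau equation (chaotic and time-periodic
  regimes) for the scramble-and-recover protocol — the known mesh
  coordinate is deliberately concealed and must be rediscovered;
* a mean-coupled Stuart-Landau ensemble (`K=1.2, ω₀=0.2`, frequencies
  spread over `2γ`) with full Floquet/monodromy machinery and a collective
  Hopf bifurcation at `γ_H ≈ 1.75`;
* a heterogeneous Hodgkin-Huxley-type network on a Chung-Lu random graph
  (a pre-Bötzinger complex caricature) with a two-dimensional emergent
  space.

## Worked example

Recover the concealed mesh coordinate of a chaotic Ginzburg-Landau field
from scrambled single-site time series, then check it against the hidden
truth:

```python
import numpy as np
from empde import (make_scrambled_pde_problem, embed_features,
                   circular_coordinate)
from empde.analysis import circular_rank_correlation

prob = make_scrambled_pde_problem("cgle", n_agents=128, seed=0,
                                  t_burn=300.0, t_sample=20.0, dt=0.02)
feats = prob.data.states.reshape(128, -1)      # one row per agent
dr = embed_features(feats, eps="nn_median",
                    selection_params={"threshold": 0.5, "max_modes": 2})
print("independent modes:", dr.selected)
angle = circular_coordinate(dr.scaled_modes[:, 0], dr.scaled_modes[:, 1])
hidden = 2 * np.pi * prob.truth["x_hidden"] / prob.truth["L"]
print("circular rank correlation:",
      round(circular_rank_correlation(angle.values, hidden), 4))
```

Output:

```
independent modes: [1, 2]
circular rank correlation: 1.0
```

Two independent diffusion modes are found, spanning a circle (the domain is
periodic); the angle on that circle is one-to-one with the concealed mesh
position, with only the circle's arbitrary rotation and orientation left
undetermined.

The same workflow runs from the shell via configuration files; one YAML per
benchmark experiment, with all model constants filled in, lives in
`configs/`:

```sh
empde run --config configs/sl_fixed_gamma.yaml --seed 0 --out runs/sl
empde run --config configs/sl_gamma_sweep.yaml --stages sample,embed --seed 1
empde toy scrambled_cgle --seed 0 --out toys/
```

Each stage writes an HDF5/CSV/JSON artifact plus a manifest of content
hashes; re-running with the same config and seed reproduces identical
artifacts.

## Layout

| Module | Role |
| --- | --- |
| `empde.simulators` | CGLE (spectral ETD2 / stiff finite differences), Stuart-Landau ensemble + analytic Jacobian, limit cycles, monodromy/Floquet, Chung-Lu graphs, Hodgkin-Huxley network |
| `empde.sampling` | attractor anchors, scaling and Floquet-direction perturbations, transient datasets, forward-difference targets |
| `empde.emergent_coords` | diffusion maps, harmonic rejection, circular coordinates, mode scaling |
| `empde.regrid` | 1D spline and 2D local-polynomial regridding onto uniform emergent grids |
| `empde.pde_learning` | finite-difference stencils and feature stacks, the MLP right-hand side, Adam training with plateau schedule |
| `empde.rollout` | SVD filter, corridor boundary conditions, forward-Euler / RK45 integration of learned models |
| `empde.analysis` | attractor distances, bifurcation scans, Hopf location, variance fractions, coordinate calibration |
| `empde.synthetic_benchmarks` | toy problems with planted ground truth |
| `empde.pipeline` / `empde.cli` | configuration-driven orchestration, HDF5 artifacts, `empde` command |
| `empde.experiments` | desk-scale reference runs of each benchmark |

See `docs/methods.md` for the science: model definitions, sampling
protocols, kernel-scale heuristics, training configuration, and the known
limitations.
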