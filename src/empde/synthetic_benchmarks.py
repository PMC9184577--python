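"""Self-contained toy problems with known answers.

These scaffold end-to-end tests of the scramble-and-recover protocol: a PDE
(or oscillator ensemble) with a *known* hidden coordinate is simulated, the
agent order is randomly permuted to conceal that coordinate, and the pipeline
must recover it (and, for the PDE toys, the right-hand side) from the time
series alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numpy.typing import NDArray

from .simulators import CGLEParams, SLEnsembleParams, TrajectoryEnsemble, \
    simulate_cgle, simulate_sl_ensemble

__all__ = ["ToyProblem", "make_scrambled_pde_problem", "make_heterogeneity_problem",
           "heat_equation_snapshots"]


@dataclass
class ToyProblem:
    """A generated dataset plus its planted ground truth."""

    name: str
    data: TrajectoryEnsemble
    truth: dict = field(default_factory=dict)


def heat_equation_snapshots(
    n_mesh: int = 64,
    n_runs: int = 8,
    n_steps: int = 60,
    dt: float = 0.01,
    diffusivity: float = 1.0,
    n_modes: int = 6,
    seed: int = 0,
) -> tuple[NDArray, NDArray, NDArray]:
    """Exact solutions of the periodic heat equation u_t = D u_xx on [0, 2*pi).

    Each run starts from a random band-limited profile; snapshots are exact
    (spectral decay of each Fourier mode), so the analytic right-hand side
    D u_xx is available for every snapshot.

    Returns (x, fields, rhs) with fields of shape (runs, steps+1, n_mesh, 1)
    and rhs matching fields (the analytic time derivative at each snapshot).
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(0.0, 2.0 * np.pi, n_mesh, endpoint=False)
    k = np.fft.fftfreq(n_mesh, d=1.0 / n_mesh)  # integer wavenumbers
    decay = -diffusivity * k**2
    fields = np.empty((n_runs, n_steps + 1, n_mesh, 1))
    rhs = np.empty_like(fields)
    for r in range(n_runs):
        coef = np.zeros(n_mesh, complex)
        live = np.abs(k) <= n_modes
        coef[live] = rng.standard_normal(live.sum()) + 1j * rng.standard_normal(live.sum())
        coef[0] = coef[0].real
        coef /= n_modes
        for j in range(n_steps + 1):
            ck = coef * np.exp(decay * j * dt)
            u = np.fft.ifft(ck * n_mesh).real / np.sqrt(n_mesh)
            du = np.fft.ifft(decay * ck * n_mesh).real / np.sqrt(n_mesh)
            fields[r, j, :, 0] = u
            rhs[r, j, :, 0] = du
    return x, fields, rhs


def make_scrambled_pde_problem(
    base: str = "cgle",
    n_agents: int = 128,
    seed: int = 0,
    t_sample: float = 20.0,
    dt: float = 0.02,
    t_burn: float = 200.0,
    n_runs: int = 1,
    params: Optional[CGLEParams] = None,
) -> ToyProblem:
    """Simulate a PDE on a hidden periodic mesh and scramble the agent order.

    ``n_runs`` independent realizations (same mesh, different random initial
    conditions) are concatenated along time before scrambling, mirroring the
    multi-run embedding protocol of the chaotic benchmark. The returned
    truth records the hidden mesh coordinate and the permutation (recorded
    and invertible), so embedding results can be checked for one-to-oneness
    with the concealed location.
    """
    if n_agents < 32:
        raise ValueError("need at least 32 agents")
    rng = np.random.default_rng(seed)
    if base == "cgle":
        params = params or CGLEParams(c1=0.0, c2=-3.0, L=80.0, n_mesh=n_agents,
                                      dt_sample=dt)
        runs = []
        for r in range(n_runs):
            run_seed = int(rng.integers(2**31))
            runs.append(simulate_cgle(params, seed=run_seed, t_burn=t_burn,
                                      t_sample=t_sample))
        states = np.concatenate([tr.states for tr in runs], axis=1)
        times = np.arange(states.shape[1]) * dt
        traj = TrajectoryEnsemble(times, states, runs[0].meta)
        x = params.x
    elif base == "heat":
        x_mesh, fields, _ = heat_equation_snapshots(
            n_mesh=n_agents, n_runs=4, n_steps=int(round(t_sample / dt)), dt=dt,
            seed=seed,
        )
        stacked = np.concatenate([f.transpose(1, 0, 2) for f in fields], axis=1)
        # agents x time x 1 channel; concatenated runs
        times = np.arange(stacked.shape[1]) * dt
        traj = TrajectoryEnsemble(times, stacked, {"system": "heat_toy"})
        x = x_mesh
    else:
        raise ValueError(f"unknown base {base!r}")
    perm = rng.permutation(n_agents)
    scrambled = TrajectoryEnsemble(
        traj.times, traj.states[perm], {**traj.meta, "scrambled": True}
    )
    return ToyProblem(
        name=f"scrambled_{base}",
        data=scrambled,
        truth={
            "x_hidden": x[perm],
            "permutation": perm,
            "inverse_permutation": np.argsort(perm),
            "L": float(x[-1] + (x[1] - x[0])),
        },
    )


def make_heterogeneity_problem(
    n_agents: int = 64,
    seed: int = 0,
    K: float = 1.2,
    gamma: float = 1.7,
    omega0: float = 0.2,
    t_span: tuple[float, float] = (0.0, 60.0),
    t_keep: Optional[float] = None,
    dt: float = 0.05,
) -> ToyProblem:
    """Stuart-Landau ensemble whose intrinsic frequencies are the planted
    heterogeneity coordinate.

    The window deliberately includes the relaxation transient: each
    oscillator's approach to the collective rotating wave depends strongly
    on its intrinsic frequency, which is what makes the heterogeneity
    visible to the embedding. ``t_keep`` optionally restricts to the final
    part of the window.
    """
    if n_agents < 32:
        raise ValueError("need at least 32 agents")
    params = SLEnsembleParams(K=K, gamma=gamma, omega0=omega0, n_osc=n_agents)
    traj = simulate_sl_ensemble(params, seed=seed, t_span=t_span, dt_sample=dt)
    if t_keep is not None:
        keep = traj.times >= t_span[1] - t_keep
        traj = TrajectoryEnsemble(traj.times[keep], traj.states[:, keep, :], traj.meta)
    return ToyProblem(
        name="sl_heterogeneity",
        data=traj,
        truth={"omega": params.omegas, "params": params},
    )
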