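"""Training/validation transient sampling near attractors.

The learned PDE is only trustworthy where it has seen data, so transients are
sampled on the slow manifold around each attractor: snapshots on the limit set
are perturbed (by uniform scaling, or along the leading stable Floquet
direction) and integrated forward, producing trajectories that relax back to
the attractor. Forward finite differences in time provide the supervised
targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.typing import NDArray

from .simulators import (
    CGLEParams,
    FloquetResult,
    HHNetworkParams,
    LimitCycle,
    NoCycleError,
    SLEnsembleParams,
    TrajectoryEnsemble,
    _cgle_random_ic,
    compute_monodromy,
    find_limit_cycle,
    propagate_floquet_direction,
    rescale_hh,
    simulate_cgle,
    simulate_hh_network,
    simulate_sl_ensemble,
    sl_jacobian,
)

__all__ = [
    "SamplingPlan",
    "TransientDataset",
    "perturb_by_scaling",
    "perturb_along_floquet",
    "estimate_time_derivative",
    "generate_transient_dataset",
]


@dataclass
class SamplingPlan:
    """How to place anchors on the attractor and perturb off it.

    Parameters mirror the per-system sampling protocols; any field not used
    by a protocol is ignored there.
    """

    n_lc: int = 20  # anchor points for training
    n_test: int = 2  # anchor points / runs held out for validation
    perturb_mode: str = "scale_factors"  # or "floquet_direction"
    factors: tuple[float, ...] = (0.9, 1.1)
    eps_perturb: float = 0.1
    horizon: float = 20.0
    dt: float = 0.02
    d_tau: float = 100.0
    t_min: float = 2000.0

    def __post_init__(self) -> None:
        n_steps = self.horizon / self.dt
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("horizon must be an integer multiple of dt")
        if self.perturb_mode == "scale_factors" and set(self.factors) == {1.0}:
            raise ValueError("scaling factors {1} perturb nothing")


@dataclass
class TransientDataset:
    """A bag of transient trajectories with train/validation tags."""

    trajectories: list[TrajectoryEnsemble]
    split: list[str]  # "train" | "val" per trajectory
    gamma_values: Optional[list[float]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.split) != len(self.trajectories):
            raise ValueError("split tags must match trajectories")
        if self.gamma_values is not None and len(self.gamma_values) != len(self.trajectories):
            raise ValueError("gamma_values must match trajectories")
        agents = {t.n_agents for t in self.trajectories}
        dts = {round(t.dt, 12) for t in self.trajectories}
        if len(agents) > 1 or len(dts) > 1:
            raise ValueError("all trajectories must share dt and agent count")

    def subset(self, tag: str) -> list[TrajectoryEnsemble]:
        return [t for t, s in zip(self.trajectories, self.split) if s == tag]

    def n_pairs(self, tag: str) -> int:
        """Number of (snapshot, d/dt snapshot) pairs available for ``tag``."""
        return sum(t.times.size - 1 for t in self.subset(tag))


# ---------------------------------------------------------------------------
# Perturbations
# ---------------------------------------------------------------------------


def perturb_by_scaling(snapshot: NDArray, factor: float) -> NDArray:
    """Scale every channel of a snapshot by a constant factor ``p > 0``."""
    if factor <= 0:
        raise ValueError("scaling factor must be positive")
    return factor * np.asarray(snapshot)


def leading_stable_direction(fr: FloquetResult, tol_neutral: float = 0.05) -> NDArray[np.float64]:
    """Real part of the unit-normalized leading stable Floquet eigenvector.

    The neutral multiplier (lambda ~ 1, tangent to the cycle) is skipped; the
    next multiplier pair spans the slow stable manifold transverse to the
    cycle.
    """
    mags = np.abs(fr.multipliers)
    nontrivial = np.nonzero(np.abs(mags - 1.0) > tol_neutral)[0]
    if nontrivial.size == 0:
        raise ValueError("no nontrivial stable direction in the Floquet spectrum")
    v = fr.directions[:, nontrivial[0]]
    v = v / np.linalg.norm(v)
    vr = np.real(v)
    return vr / np.linalg.norm(vr)


def perturb_along_floquet(
    lc: LimitCycle, fr: FloquetResult, eps: float = 0.1
) -> list[NDArray[np.float64]]:
    """Three initial states at the cycle anchor: W - eps v1, W, W + eps v1.

    ``v1`` is the (real part of the) leading stable Floquet direction,
    reshaped to (agents, channels) to match the anchor snapshot.
    """
    v1 = leading_stable_direction(fr)
    n = lc.anchor.shape[0]
    dv = np.stack([v1[:n], v1[n:]], axis=-1)  # (agents, 2)
    return [lc.anchor - eps * dv, lc.anchor.copy(), lc.anchor + eps * dv]


# ---------------------------------------------------------------------------
# Time-derivative targets
# ---------------------------------------------------------------------------


def estimate_time_derivative(
    traj: TrajectoryEnsemble, dt: Optional[float] = None
) -> NDArray[np.float64]:
    """Forward-difference targets (W(t+dt) - W(t)) / dt per agent/channel.

    Returns an array of shape (agents, timesteps - 1, channels); the final
    snapshot has no forward difference and is dropped from the inputs.
    """
    if traj.times.size < 2:
        raise ValueError("need at least two consecutive samples")
    if dt is not None and abs(traj.dt - dt) > 1e-9 * max(1.0, abs(dt)):
        raise ValueError(f"trajectory dt {traj.dt} does not match requested dt {dt}")
    h = traj.dt
    return np.diff(traj.states.astype(float), axis=1) / h


# ---------------------------------------------------------------------------
# Per-system protocols
# ---------------------------------------------------------------------------


def _snapshot_to_complex(snapshot: NDArray) -> NDArray[np.complex128]:
    return snapshot[:, 0] + 1j * snapshot[:, 1]


def _cgle_chaotic_protocol(
    plan: SamplingPlan,
    params: CGLEParams,
    seed: int,
    t_burn: float,
    noise_sigma: float,
    store_dtype,
    dt_burn: float,
) -> TransientDataset:
    """Independent runs, noise-perturbed, sampled for ``horizon`` time units."""
    rng = np.random.default_rng(seed)
    n_total = plan.n_lc + plan.n_test
    trajectories, split = [], []
    for i in range(n_total):
        run_seed = int(rng.integers(2**31))
        base = simulate_cgle(
            params, seed=run_seed, t_burn=t_burn, t_sample=0.0, dt_burn=dt_burn
        )
        W0 = _snapshot_to_complex(base.snapshot(-1))
        W0 = W0 + noise_sigma * (
            rng.standard_normal(params.n_mesh) + 1j * rng.standard_normal(params.n_mesh)
        )
        traj = simulate_cgle(params, ic=W0, t_burn=0.0, t_sample=plan.horizon,
                             dt_burn=dt_burn)
        traj.states = traj.states.astype(store_dtype)
        trajectories.append(traj)
        split.append("train" if i < plan.n_lc else "val")
    return TransientDataset(trajectories, split, meta={"system": "cgle_chaotic"})


def _cgle_noflux_protocol(
    plan: SamplingPlan,
    params: CGLEParams,
    seed: int,
    n_keep_agents: Optional[int],
    store_dtype,
) -> TransientDataset:
    """Anchors along the settled periodic orbit, scaled by the plan factors."""
    x = params.x
    W0 = (1.0 + np.cos(np.pi * x / params.L)) / 2.0
    n_total = plan.n_lc + plan.n_test
    span = plan.d_tau * (n_total - 1)
    base = simulate_cgle(
        params.__class__(**{**params.__dict__, "dt_sample": plan.d_tau}),
        ic=W0.astype(complex),
        t_burn=plan.t_min,
        t_sample=span,
    )
    stride = 1
    if n_keep_agents is not None and n_keep_agents < params.n_mesh:
        stride = params.n_mesh // n_keep_agents
    sample_params = params.__class__(**{**params.__dict__, "dt_sample": plan.dt})
    trajectories, split = [], []
    for i in range(n_total):
        anchor = _snapshot_to_complex(base.snapshot(i))
        for p in plan.factors:
            traj = simulate_cgle(sample_params, ic=p * anchor, t_burn=0.0,
                                 t_sample=plan.horizon)
            traj.times = base.times[i] + traj.times
            traj = TrajectoryEnsemble(
                traj.times, traj.states[::stride].astype(store_dtype), traj.meta
            )
            trajectories.append(traj)
            split.append("train" if i < plan.n_lc else "val")
    return TransientDataset(trajectories, split, meta={"system": "cgle_noflux"})


def _sl_anchor_directions(
    params: SLEnsembleParams,
    plan: SamplingPlan,
    seed: int,
    settle_time: float,
    monodromy_steps: int,
    n_anchors: int,
):
    """Anchors on the SL limit set plus slow stable directions at each.

    On a limit cycle, the monodromy matrix at one anchor yields the leading
    stable eigendirection; it is transported to the other anchors with the
    variational equation. When the attractor is the fixed point W = 0
    (oscillator death), the slow stable eigenspace of the analytic Jacobian
    at the origin is used with seeded random phases instead.
    """
    settle = simulate_sl_ensemble(
        params, seed=seed, t_span=(0.0, settle_time), dt_sample=0.05
    )
    tail_idx = settle.times >= settle_time * 0.75
    tail = TrajectoryEnsemble(
        settle.times[tail_idx], settle.states[:, tail_idx, :], settle.meta
    )
    rng = np.random.default_rng(seed + 1)
    n = params.n_osc
    try:
        lc = find_limit_cycle(tail)
        fr = compute_monodromy(lc, params, n_steps=monodromy_steps)
        v0 = leading_stable_direction(fr)
        taus = np.arange(n_anchors) * lc.period / n_anchors
        dirs = propagate_floquet_direction(lc, params, v0, taus)
        from scipy.interpolate import CubicSpline

        flat = tail.states.transpose(1, 0, 2).reshape(tail.times.size, -1)
        spline = CubicSpline(tail.times - tail.times[0], flat, axis=0)
        anchors = [spline(tau).reshape(n, 2) for tau in taus]
        return anchors, [d for d in dirs], lc, fr
    except NoCycleError:
        J = sl_jacobian(np.zeros(n, complex), params)
        vals, vecs = np.linalg.eig(J)
        order = np.argsort(-vals.real)  # slowest decay first
        stable = order[vals.real[order] < 0]
        if stable.size == 0:
            raise
        v = vecs[:, stable[0]]
        anchors, dirs = [], []
        for _ in range(n_anchors):
            phase = rng.uniform(0.0, 2.0 * np.pi)
            d = np.real(np.exp(1j * phase) * v)
            dirs.append(d / np.linalg.norm(d))
            anchors.append(np.zeros((n, 2)))
        return anchors, dirs, None, None


def _sl_floquet_protocol(
    plan: SamplingPlan,
    params: SLEnsembleParams,
    seed: int,
    settle_time: float,
    monodromy_steps: int,
    store_dtype,
) -> TransientDataset:
    n = params.n_osc
    n_total = plan.n_lc + plan.n_test
    anchors, dirs, lc, fr = _sl_anchor_directions(
        params, plan, seed, settle_time, monodromy_steps, n_total
    )
    trajectories, split = [], []
    for i, (anchor, d) in enumerate(zip(anchors, dirs)):
        dv = np.stack([d[:n], d[n:]], axis=-1)
        for ic_state in (anchor - plan.eps_perturb * dv, anchor, anchor + plan.eps_perturb * dv):
            W0 = _snapshot_to_complex(ic_state)
            traj = simulate_sl_ensemble(
                params, ic=W0, t_span=(0.0, plan.horizon), dt_sample=plan.dt
            )
            traj.states = traj.states.astype(store_dtype)
            trajectories.append(traj)
            split.append("train" if i < plan.n_lc else "val")
    meta = {"system": "sl", "period": None if lc is None else lc.period}
    return TransientDataset(trajectories, split, meta=meta)


def _hh_protocol(
    plan: SamplingPlan,
    params: HHNetworkParams,
    seed: int,
    store_dtype,
    rtol: float,
    atol: float,
) -> TransientDataset:
    """Attractor window plus scaled-snapshot transients, in rescaled (V, h).

    The scaling perturbation acts on the rescaled coordinates, where both
    channels share one scale; the perturbed state is mapped back to physical
    units for integration.
    """
    from .simulators import unscale_hh

    base = simulate_hh_network(params, rtol=rtol, atol=atol)
    base_rs = rescale_hh(base)
    base_rs.states = base_rs.states.astype(store_dtype)
    n_total = plan.n_lc + plan.n_test
    n_t = base.times.size
    anchor_ids = np.linspace(0, n_t - 1, n_total + 1)[:-1].astype(int)
    trajectories = [base_rs]
    split = ["train"]
    for i, j in enumerate(anchor_ids):
        snap_rs = base_rs.snapshot(int(j)).astype(float)
        for p in plan.factors:
            pert = perturb_by_scaling(snap_rs, p)
            phys = np.stack(
                [
                    pert[:, 0] * 30.0 - 37.0,
                    pert[:, 1] * 0.2 + 0.42,
                ],
                axis=-1,
            )
            ic = np.concatenate([phys[:, 0], phys[:, 1]])
            t0 = float(base.times[j])
            traj = simulate_hh_network(
                params,
                t_span=(t0, t0 + plan.horizon),
                t_min=t0,
                dt_sample=plan.dt,
                ic=ic,
                rtol=rtol,
                atol=atol,
            )
            traj_rs = rescale_hh(traj)
            traj_rs.states = traj_rs.states.astype(store_dtype)
            trajectories.append(traj_rs)
            split.append("train" if i < plan.n_lc else "val")
    return TransientDataset(trajectories, split, meta={"system": "hh"})


def generate_transient_dataset(
    system: str,
    plan: SamplingPlan,
    seed: int = 0,
    params=None,
    gamma_values: Optional[Sequence[float]] = None,
    store_dtype=np.float32,
    **options,
) -> TransientDataset:
    """Execute the per-system transient-sampling protocol.

    Parameters
    ----------
    system
        One of ``cgle_chaotic``, ``cgle_noflux``, ``sl``, ``sl_gamma_sweep``,
        ``hh``.
    plan
        Anchor counts, perturbation sizes and sampling cadence.
    gamma_values
        For ``sl_gamma_sweep``: the half-width values to sample; the protocol
        is repeated per value and each trajectory is tagged with its gamma.
    options
        System-specific knobs: ``t_burn``/``noise_sigma``/``dt_burn``
        (chaotic CGLE), ``n_keep_agents`` (no-flux CGLE downsampling),
        ``settle_time``/``monodromy_steps`` (Stuart-Landau),
        ``rtol``/``atol`` (Hodgkin-Huxley).
    """
    if system == "cgle_chaotic":
        params = params or CGLEParams(c1=0.0, c2=-3.0, L=80.0, dt_sample=plan.dt)
        ds = _cgle_chaotic_protocol(
            plan,
            params,
            seed,
            t_burn=options.get("t_burn", 1000.0),
            noise_sigma=options.get("noise_sigma", 0.1),
            store_dtype=store_dtype,
            dt_burn=options.get("dt_burn", 0.05),
        )
    elif system == "cgle_noflux":
        params = params or CGLEParams(
            c1=1.0, c2=2.0, L=200.0, boundary="no_flux", dt_sample=plan.dt
        )
        ds = _cgle_noflux_protocol(
            plan, params, seed, options.get("n_keep_agents", 128), store_dtype
        )
    elif system == "sl":
        params = params or SLEnsembleParams(K=1.2, gamma=1.7, omega0=0.2, n_osc=512)
        ds = _sl_floquet_protocol(
            plan,
            params,
            seed,
            settle_time=options.get("settle_time", 400.0),
            monodromy_steps=options.get("monodromy_steps", 1024),
            store_dtype=store_dtype,
        )
    elif system == "sl_gamma_sweep":
        if gamma_values is None:
            gamma_values = np.linspace(1.7, 1.8, 6)
        base = params or SLEnsembleParams(K=1.2, gamma=1.7, omega0=0.2, n_osc=512)
        all_traj, all_split, all_gamma = [], [], []
        for i, g in enumerate(gamma_values):
            pg = SLEnsembleParams(K=base.K, gamma=float(g), omega0=base.omega0,
                                  n_osc=base.n_osc)
            sub = _sl_floquet_protocol(
                plan,
                pg,
                seed + i,
                settle_time=options.get("settle_time", 400.0),
                monodromy_steps=options.get("monodromy_steps", 1024),
                store_dtype=store_dtype,
            )
            all_traj.extend(sub.trajectories)
            all_split.extend(sub.split)
            all_gamma.extend([float(g)] * len(sub.trajectories))
        ds = TransientDataset(
            all_traj, all_split, gamma_values=all_gamma, meta={"system": "sl_gamma_sweep"}
        )
    elif system == "hh":
        if params is None:
            params = HHNetworkParams.random(seed=seed)
        ds = _hh_protocol(
            plan,
            params,
            seed,
            store_dtype,
            rtol=options.get("rtol", 1e-6),
            atol=options.get("atol", 1e-8),
        )
    else:
        raise ValueError(f"unknown system {system!r}")

    ds.meta.update(
        {
            "seed": seed,
            "n_train_pairs": ds.n_pairs("train"),
            "n_val_pairs": ds.n_pairs("val"),
        }
    )
    return ds
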