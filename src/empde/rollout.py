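"""Integrate the learned PDE forward in time.

Because the learned right-hand side is only trusted where training data
existed, inference combines three safeguards:

* narrow boundary corridors of ground-truth values replace analytic boundary
  conditions in the (non-periodic) emergent domain;
* a truncated-SVD filter projects every emitted snapshot back onto the
  subspace spanned by the training data;
* a norm cap aborts a diverging rollout with the last stable time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.typing import NDArray
from scipy.integrate import solve_ivp

from .pde_learning import PDEModel, predict_rhs
from .regrid import EmergentGrid, GriddedField
from .simulators import DivergedSimulationError

__all__ = ["SVDFilter", "RolloutConfig", "fit_svd_filter", "apply_svd_filter",
           "integrate_learned_pde"]


@dataclass
class SVDFilter:
    """Orthonormal basis of the leading left-singular training directions."""

    basis: NDArray[np.float64]  # (dim, n_keep)
    singular_values: NDArray[np.float64]  # all singular values, descending

    @property
    def n_keep(self) -> int:
        return self.basis.shape[1]

    def variance_fraction(self) -> float:
        s2 = self.singular_values**2
        return float(s2[: self.n_keep].sum() / s2.sum())


def fit_svd_filter(snapshots: NDArray[np.float64], n_keep: int) -> SVDFilter:
    """SVD of the training snapshot matrix (snapshots as rows, no centering).

    The basis spans the ``n_keep`` leading right-singular directions of the
    snapshot matrix, i.e. the subspace in which the training data lives.
    """
    M = np.asarray(snapshots, float)
    if M.ndim != 2 or M.size == 0:
        raise ValueError("snapshot matrix must be nonempty and 2D")
    # rows = snapshots; the snapshot-space basis is the right-singular one
    _, s, Vt = np.linalg.svd(M, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12))
    if n_keep > rank:
        raise ValueError(f"n_keep={n_keep} exceeds the data rank {rank}")
    return SVDFilter(basis=Vt[:n_keep].T.copy(), singular_values=s)


def apply_svd_filter(filt: SVDFilter, snapshot: NDArray[np.float64]) -> NDArray:
    """Project a snapshot onto the training subspace (idempotent)."""
    shape = snapshot.shape
    flat = np.asarray(snapshot, float).ravel()
    if flat.size != filt.basis.shape[0]:
        raise ValueError("snapshot dimension does not match the filter basis")
    return (filt.basis @ (filt.basis.T @ flat)).reshape(shape)


@dataclass
class RolloutConfig:
    """Time stepping, boundary handling and filtering during inference."""

    dt: float = 2e-3
    scheme: str = "forward_euler"  # or "rk45"
    boundary: str = "corridor"  # or "periodic"
    corridor_width: int = 4
    filter: Optional[SVDFilter] = None
    filter_every: int = 1

    def validate(self, stencil_length: int) -> None:
        hw = (stencil_length - 1) // 2
        if self.boundary == "corridor" and self.corridor_width < hw:
            raise ValueError(
                f"corridor width {self.corridor_width} below stencil half-width {hw}"
            )


def _corridor_mask(shape: tuple[int, ...], width: int) -> NDArray[np.bool_]:
    """True on the corridor cells: both ends in 1D, a frame in 2D."""
    mask = np.zeros(shape, dtype=bool)
    for axis in range(len(shape)):
        sl_lo = [slice(None)] * len(shape)
        sl_hi = [slice(None)] * len(shape)
        sl_lo[axis] = slice(0, width)
        sl_hi[axis] = slice(shape[axis] - width, shape[axis])
        mask[tuple(sl_lo)] = True
        mask[tuple(sl_hi)] = True
    return mask


def integrate_learned_pde(
    model: PDEModel,
    ic: NDArray[np.float64],
    cfg: RolloutConfig,
    horizon: float,
    bc_source: Optional[NDArray[np.float64]] = None,
    gamma: Optional[float] = None,
    grid: Optional[EmergentGrid] = None,
    rhs_override=None,
    norm_cap: float = 1e3,
) -> GriddedField:
    """Roll the learned PDE out from a gridded initial snapshot.

    Parameters
    ----------
    ic
        Initial snapshot, shape (*grid_shape, channels).
    bc_source
        Ground-truth trajectory aligned in time with the rollout, shape
        (n_steps + 1, *grid_shape, channels); required in corridor mode.
        After every step the corridor cells are overwritten from it.
    rhs_override
        Optional callable ``(snapshot, gamma) -> d/dt`` replacing the
        network (used to exercise the integrator against an oracle RHS).
    gamma
        Parameter value forwarded to a parameter-aware model.

    Returns a :class:`GriddedField` holding the emitted snapshots at every
    step (including the initial one).
    """
    spec = model.spec
    cfg.validate(spec.stencil_length)
    n_steps = int(round(horizon / cfg.dt))
    shape = ic.shape
    grid_shape = shape[:-1]
    if cfg.boundary == "corridor":
        if bc_source is None:
            raise ValueError("corridor mode requires a bc_source trajectory")
        if bc_source.shape[0] < n_steps + 1 or bc_source.shape[1:] != shape:
            raise ValueError("bc_source must supply n_steps+1 aligned snapshots")
        mask = _corridor_mask(grid_shape, cfg.corridor_width)
    elif spec.boundary != "periodic":
        raise ValueError("periodic rollout requires a periodic model")

    def rhs(snapshot: NDArray) -> NDArray:
        if rhs_override is not None:
            return rhs_override(snapshot, gamma)
        return predict_rhs(model, snapshot, gamma=gamma)

    def postprocess(u: NDArray, step: int) -> NDArray:
        if cfg.boundary == "corridor":
            u[mask] = bc_source[step][mask]
        if cfg.filter is not None and step % cfg.filter_every == 0:
            u = apply_svd_filter(cfg.filter, u)
        return u

    out = np.empty((n_steps + 1,) + shape)
    u = np.array(ic, float)
    out[0] = u

    if cfg.scheme == "forward_euler":
        for step in range(1, n_steps + 1):
            u = u + cfg.dt * rhs(u)
            u = postprocess(u, step)
            if not np.all(np.isfinite(u)) or np.max(np.abs(u)) > norm_cap:
                raise DivergedSimulationError(
                    f"learned-PDE rollout diverged; last stable t = {(step - 1) * cfg.dt:.4g}"
                )
            out[step] = u
    elif cfg.scheme == "rk45":
        if cfg.boundary == "corridor":
            raise ValueError("rk45 rollout supports periodic boundaries only")

        def f(t, y):
            return rhs(y.reshape(shape)).ravel()

        t_eval = np.arange(n_steps + 1) * cfg.dt
        sol = solve_ivp(f, (0.0, t_eval[-1]), u.ravel(), method="RK45",
                        t_eval=t_eval, rtol=1e-6, atol=1e-8)
        if not sol.success:
            raise DivergedSimulationError("learned-PDE rk45 rollout failed")
        for step in range(n_steps + 1):
            snap = sol.y[:, step].reshape(shape)
            if cfg.filter is not None:
                snap = apply_svd_filter(cfg.filter, snap)
            out[step] = snap
        if not np.all(np.isfinite(out)) or np.max(np.abs(out)) > norm_cap:
            raise DivergedSimulationError("learned-PDE rk45 rollout diverged")
    else:
        raise ValueError(f"unknown scheme {cfg.scheme!r}")

    times = np.arange(n_steps + 1) * cfg.dt
    gf_grid = grid if grid is not None else EmergentGrid(
        axes=[np.arange(s, dtype=float) for s in grid_shape],
        periodic=tuple(spec.boundary == "periodic" for _ in grid_shape),
    )
    return GriddedField(gf_grid, out, times=times, meta={"scheme": cfg.scheme})
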