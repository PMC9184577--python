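"""Quantitative diagnostics for learned-PDE experiments.

Distances of transients to an attractor, bifurcation scans over the
frequency-spread parameter gamma (true ODE vs learned PDE), localization of
the collective Hopf point, SVD variance capture and calibration of emergent
coordinates against known agent heterogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.spatial.distance import cdist
from scipy.stats import spearmanr

from .simulators import (
    DivergedSimulationError,
    NoCycleError,
    SLEnsembleParams,
    TrajectoryEnsemble,
    compute_monodromy,
    find_limit_cycle,
    simulate_sl_ensemble,
    sl_jacobian,
)
from .sampling import leading_stable_direction

__all__ = [
    "BifurcationResult",
    "attractor_distance",
    "bifurcation_scan",
    "sl_limit_amplitude",
    "make_true_sl_engine",
    "locate_transition",
    "svd_variance_fraction",
    "coordinate_calibration",
    "circular_rank_correlation",
]


@dataclass
class BifurcationResult:
    """Mean limit-set amplitude per scanned gamma for one engine."""

    gamma_grid: NDArray[np.float64]
    mean_limit_amplitude: NDArray[np.float64]
    engine: str = "true_ode"
    horizon: float = 10000.0

    def __post_init__(self) -> None:
        amps = self.mean_limit_amplitude
        if np.any(amps[np.isfinite(amps)] < 0):
            raise ValueError("amplitudes must be nonnegative")


def attractor_distance(
    traj_flat: NDArray[np.float64], attractor_flat: NDArray[np.float64]
) -> NDArray[np.float64]:
    """d(t) = min over attractor samples of the stacked-real Euclidean distance.

    Both arrays are (timesteps, dim) / (samples, dim); complex ensembles are
    compared in C^N through their stacked real coordinates, which gives the
    identical metric.
    """
    if attractor_flat.size == 0:
        raise ValueError("empty attractor sample set")
    D = cdist(np.asarray(traj_flat, float), np.asarray(attractor_flat, float))
    return D.min(axis=1)


def _sl_slow_direction(params: SLEnsembleParams, settle_time: float,
                       seed: int, monodromy_steps: int) -> NDArray[np.float64]:
    """Slow stable direction transverse to the gamma-dependent limit set.

    Uses the monodromy matrix when the settled state is a cycle, else the
    slowest stable eigendirection of the Jacobian at the origin.
    """
    settle = simulate_sl_ensemble(params, seed=seed, t_span=(0.0, settle_time),
                                  dt_sample=0.05)
    idx = settle.times >= 0.75 * settle_time
    tail = TrajectoryEnsemble(settle.times[idx], settle.states[:, idx, :], settle.meta)
    n = params.n_osc
    try:
        lc = find_limit_cycle(tail)
        fr = compute_monodromy(lc, params, n_steps=monodromy_steps)
        return leading_stable_direction(fr)
    except NoCycleError:
        J = sl_jacobian(np.zeros(n, complex), params)
        vals, vecs = np.linalg.eig(J)
        stable = np.nonzero(vals.real < 0)[0]
        k = stable[np.argmax(vals.real[stable])]
        v = np.real(vecs[:, k])
        return v / np.linalg.norm(v)


def sl_limit_amplitude(
    params: SLEnsembleParams,
    horizon: float,
    seed: int,
    eps: float = 0.05,
    settle_time: float = 200.0,
    monodromy_steps: int = 512,
    direction: Optional[NDArray[np.float64]] = None,
    return_ic: bool = False,
):
    """Ensemble-mean |W| of the final snapshot after ``horizon`` time units.

    The initial condition sits close to the limit set: the settled state is
    perturbed by ``eps`` along a slow stable direction (recomputed unless
    ``direction`` is supplied).
    """
    n = params.n_osc
    settle = simulate_sl_ensemble(params, seed=seed, t_span=(0.0, settle_time),
                                  dt_sample=0.5)
    anchor = settle.snapshot(-1)
    if direction is None:
        direction = _sl_slow_direction(params, settle_time, seed, monodromy_steps)
    dv = np.stack([direction[:n], direction[n:]], axis=-1)
    ic_state = anchor + eps * dv
    W0 = ic_state[:, 0] + 1j * ic_state[:, 1]
    run = simulate_sl_ensemble(params, ic=W0, t_span=(0.0, horizon), dt_sample=horizon / 200)
    final = run.snapshot(-1)
    amp = float(np.mean(np.hypot(final[:, 0], final[:, 1])))
    if return_ic:
        return amp, W0, run
    return amp


def make_true_sl_engine(
    base: SLEnsembleParams,
    eps: float = 0.05,
    settle_time: float = 200.0,
    monodromy_steps: int = 512,
    shared_direction: bool = True,
) -> Callable[[float, float, int], float]:
    """Scan engine over gamma for the true Stuart-Landau ODE.

    With ``shared_direction`` the slow stable direction is computed once at
    the first oscillatory gamma and reused across the scan (it varies slowly
    with gamma); otherwise it is recomputed for every gamma.
    """
    cache: dict = {}

    def engine(gamma: float, horizon: float, seed: int) -> float:
        params = SLEnsembleParams(K=base.K, gamma=float(gamma), omega0=base.omega0,
                                  n_osc=base.n_osc)
        direction = cache.get("direction") if shared_direction else None
        if direction is None:
            direction = _sl_slow_direction(params, settle_time, seed, monodromy_steps)
            if shared_direction:
                cache["direction"] = direction
        return sl_limit_amplitude(
            params, horizon, seed, eps=eps, settle_time=settle_time,
            monodromy_steps=monodromy_steps, direction=direction,
        )

    return engine


def bifurcation_scan(
    engine: Callable[[float, float, int], float],
    gamma_grid: Sequence[float],
    horizon: float = 10000.0,
    seed: int = 0,
    engine_name: str = "true_ode",
) -> BifurcationResult:
    """Record the limit-set mean amplitude for every gamma in the grid.

    ``engine(gamma, horizon, seed)`` integrates from a seeded initial
    condition close to the limit set and returns the ensemble-mean |W| of
    the final snapshot; a diverged run is recorded as NaN with a warning.
    """
    gamma_grid = np.asarray(gamma_grid, float)
    amps = np.empty_like(gamma_grid)
    for i, g in enumerate(gamma_grid):
        try:
            amps[i] = engine(float(g), horizon, seed + i)
        except DivergedSimulationError as err:
            warnings.warn(f"gamma={g}: {err}")
            amps[i] = np.nan
    return BifurcationResult(gamma_grid, amps, engine=engine_name, horizon=horizon)


def locate_transition(br: BifurcationResult, threshold: float = 0.01) -> float:
    """Gamma at which the limit-set amplitude crosses ``threshold``.

    Returns the midpoint of the bracketing grid cell (the scan's resolution
    limit); raises if no crossing is bracketed by the grid.
    """
    a = br.mean_limit_amplitude
    above = a > threshold
    crossings = np.nonzero(above[:-1] != above[1:])[0]
    if crossings.size == 0:
        raise ValueError("no amplitude-threshold crossing inside the scanned grid")
    i = int(crossings[0])
    return float(0.5 * (br.gamma_grid[i] + br.gamma_grid[i + 1]))


def svd_variance_fraction(snapshots: NDArray[np.float64], n: int) -> float:
    """Fraction of total variance captured by the top ``n`` singular modes."""
    M = np.asarray(snapshots, float)
    if M.size == 0:
        raise ValueError("empty snapshot matrix")
    # work with the smaller Gram matrix; exact singular values either way
    if M.shape[0] >= M.shape[1]:
        G = M.T @ M
    else:
        G = M @ M.T
    vals = np.linalg.eigvalsh(G)[::-1]
    vals = np.clip(vals, 0.0, None)
    return float(vals[:n].sum() / vals.sum())


def circular_rank_correlation(a: NDArray[np.float64], b: NDArray[np.float64]) -> float:
    """Strength of a circular monotone (one-to-one) relation between angles.

    Both inputs are mapped to rank angles on [0, 2*pi); the statistic is the
    larger of the phase-locking moduli |<exp(i(alpha - beta))>| and
    |<exp(i(alpha + beta))>|, so it equals 1 exactly when one angle is a
    (possibly reflected, rotated) monotone circular function of the other.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size != b.size:
        raise ValueError("inputs must have matching length")
    ra = 2.0 * np.pi * np.argsort(np.argsort(a)) / a.size
    rb = 2.0 * np.pi * np.argsort(np.argsort(b)) / b.size
    direct = np.abs(np.mean(np.exp(1j * (ra - rb))))
    reflected = np.abs(np.mean(np.exp(1j * (ra + rb))))
    return float(max(direct, reflected))


def coordinate_calibration(
    emergent_coord: NDArray[np.float64], reference: NDArray[np.float64]
) -> dict:
    """One-to-one report between an emergent coordinate and a known quantity.

    Returns the Spearman correlation, the number of monotonicity violations
    after orienting the coordinate (sign convention), and a bijectivity flag
    (strictly monotone after orientation).
    """
    x = np.asarray(emergent_coord, float)
    y = np.asarray(reference, float)
    if x.size != y.size:
        raise ValueError("agent counts differ")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant inputs cannot be calibrated")
    rho = float(spearmanr(x, y).statistic)
    sign = 1 if rho >= 0 else -1
    order = np.argsort(y)
    xs = sign * x[order]
    violations = int(np.sum(np.diff(xs) <= 0))
    return {
        "spearman": rho,
        "orientation_sign": sign,
        "monotonicity_violations": violations,
        "bijective": violations == 0,
    }
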