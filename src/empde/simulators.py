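"""Ground-truth simulators for the agent ensembles studied by the package.

Three systems are provided:

* the 1D complex Ginzburg-Landau equation (CGLE), with periodic boundaries
  solved pseudospectrally with exponential time differencing, and with
  no-flux (Neumann) boundaries solved with a three-point Laplacian and a
  stiff multistep integrator;
* a mean-coupled ensemble of Stuart-Landau oscillators, together with its
  analytic Jacobian, limit-cycle detection and Floquet (monodromy) analysis;
* a heterogeneous network of Hodgkin-Huxley type neurons coupled on a
  Chung-Lu random graph, a caricature of the pre-Boetzinger complex.

Complex states are stored as two real channels (Re, Im) everywhere; real
state vectors stack all real parts first, then all imaginary parts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional, Sequence

import numpy as np
from numpy.typing import NDArray
from scipy.integrate import solve_ivp
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

__all__ = [
    "CGLEParams",
    "SLEnsembleParams",
    "HHNetworkParams",
    "TrajectoryEnsemble",
    "LimitCycle",
    "FloquetResult",
    "DivergedSimulationError",
    "NoCycleError",
    "simulate_cgle",
    "cgle_rhs_uniform",
    "simulate_sl_ensemble",
    "sl_rhs",
    "sl_jacobian",
    "sl_jacobian_apply",
    "find_limit_cycle",
    "compute_monodromy",
    "propagate_floquet_direction",
    "build_chung_lu_adjacency",
    "chung_lu_edge_probabilities",
    "simulate_hh_network",
    "rescale_hh",
    "unscale_hh",
    "HH_V_SHIFT",
    "HH_V_SCALE",
    "HH_H_SHIFT",
    "HH_H_SCALE",
]

# Norm cap (per agent-channel RMS) above which a simulation is declared diverged.
DIVERGENCE_CAP = 1e6

# Default relative recurrence tolerance accepted for a limit cycle.
TOL_PERIOD = 1e-6


class DivergedSimulationError(RuntimeError):
    """Raised when a simulated field exceeds the norm cap."""


class NoCycleError(RuntimeError):
    """Raised when no periodic orbit can be detected in a trajectory."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class CGLEParams:
    """Parameters of the 1D complex Ginzburg-Landau equation.

    dW/dt = W + (1 + i c1) W_xx - (1 - i c2) |W|^2 W  on  x in [0, L].
    """

    c1: float
    c2: float
    L: float
    n_mesh: int = 256
    boundary: str = "periodic"  # "periodic" | "no_flux"
    dt_sample: float = 0.02

    def __post_init__(self) -> None:
        if self.n_mesh < 8:
            raise ValueError("n_mesh must be >= 8")
        if self.L <= 0:
            raise ValueError("L must be positive")
        if self.dt_sample <= 0:
            raise ValueError("dt_sample must be positive")
        if self.boundary not in ("periodic", "no_flux"):
            raise ValueError(f"unknown boundary {self.boundary!r}")

    @property
    def x(self) -> NDArray[np.float64]:
        """Mesh points: cell-left points for periodic, inclusive for no-flux."""
        if self.boundary == "periodic":
            return np.linspace(0.0, self.L, self.n_mesh, endpoint=False)
        return np.linspace(0.0, self.L, self.n_mesh)


@dataclass
class SLEnsembleParams:
    """Mean-coupled Stuart-Landau ensemble.

    dW_k/dt = (1 + i w_k) W_k - |W_k|^2 W_k + (K/N) sum_j (W_j - W_k),
    with intrinsic frequencies w_k linearly spaced in
    [omega0 - gamma, omega0 + gamma] (both endpoints included).
    """

    K: float
    gamma: float
    omega0: float = 0.0
    n_osc: int = 512

    @property
    def omegas(self) -> NDArray[np.float64]:
        return np.linspace(self.omega0 - self.gamma, self.omega0 + self.gamma, self.n_osc)


#: affine rescaling constants for Hodgkin-Huxley observables
HH_V_SHIFT, HH_V_SCALE = 37.0, 30.0
HH_H_SHIFT, HH_H_SCALE = 0.42, 0.2


@dataclass
class HHNetworkParams:
    """Heterogeneous Hodgkin-Huxley type network (pre-Boetzinger caricature).

    Each neuron carries a voltage V_k and channel variable h_k; neurons are
    coupled through a synaptic current on a symmetric Chung-Lu random graph.
    The applied currents I_app^k = 22 + 2 w_k with w_k uniform in [-1, 1]
    provide intrinsic (kinetic) heterogeneity; the graph provides structural
    heterogeneity.
    """

    n_neurons: int = 1024
    C_mem: float = 0.21
    eps_hh: float = 0.1
    g_Na: float = 2.8
    g_l: float = 2.4
    g_syn: float = 0.3
    V_Na: float = 50.0
    V_l: float = -65.0
    V_syn: float = 0.0
    chung_lu_p: float = 0.9
    chung_lu_r: float = 0.25
    I_app: Optional[NDArray[np.float64]] = None
    adjacency: Optional[NDArray[np.int8]] = None

    @classmethod
    def random(cls, n_neurons: int = 1024, seed: int = 0, **kwargs) -> "HHNetworkParams":
        """Draw applied currents and a Chung-Lu adjacency from ``seed``."""
        p = cls(n_neurons=n_neurons, **kwargs)
        rng = np.random.default_rng(seed)
        w = rng.uniform(-1.0, 1.0, n_neurons)
        p.I_app = 22.0 + 2.0 * w
        p.adjacency = build_chung_lu_adjacency(
            n_neurons, p.chung_lu_p, p.chung_lu_r, seed=rng.integers(2**31)
        )
        return p

    def validate(self) -> None:
        if self.I_app is None or self.adjacency is None:
            raise ValueError("I_app and adjacency must be set (use HHNetworkParams.random)")
        A = self.adjacency
        if A.shape != (self.n_neurons, self.n_neurons):
            raise ValueError("adjacency shape mismatch")
        if np.any(np.diag(A) != 0) or not np.array_equal(A, A.T):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if np.any(self.I_app < 20.0) or np.any(self.I_app > 24.0):
            raise ValueError("I_app entries must lie in [20, 24]")


# ---------------------------------------------------------------------------
# Trajectory container
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryEnsemble:
    """Per-agent multichannel time series on a shared time grid.

    ``states`` has shape (agents, timesteps, channels). For complex fields the
    two channels are (Re W, Im W); for the neuron network they are (V, h).
    """

    times: NDArray[np.float64]
    states: NDArray[np.float64]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.ndim != 3 or self.states.shape[1] != self.times.size:
            raise ValueError("states must have shape (agents, timesteps, channels)")
        if not np.all(np.isfinite(self.states)):
            raise ValueError("states contain non-finite entries")

    @property
    def n_agents(self) -> int:
        return self.states.shape[0]

    @property
    def n_channels(self) -> int:
        return self.states.shape[2]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def as_complex(self) -> NDArray[np.complex128]:
        """(agents, timesteps) complex view for two-channel (Re, Im) data."""
        if self.n_channels != 2:
            raise ValueError("complex view requires exactly two channels")
        return self.states[:, :, 0] + 1j * self.states[:, :, 1]

    def snapshot(self, index: int) -> NDArray[np.float64]:
        """State of all agents at one time index, shape (agents, channels)."""
        return self.states[:, index, :].copy()

    @classmethod
    def from_complex(
        cls, times: NDArray, W: NDArray[np.complex128], meta: Optional[dict] = None
    ) -> "TrajectoryEnsemble":
        """Build from a complex (agents, timesteps) array."""
        states = np.stack([W.real, W.imag], axis=-1)
        return cls(times=np.asarray(times, float), states=states, meta=meta or {})


@dataclass
class LimitCycle:
    """A detected periodic orbit: period, one-period samples and an anchor."""

    period: float
    samples: TrajectoryEnsemble
    anchor: NDArray[np.float64]  # (agents, channels)
    residual: float = 0.0  # relative recurrence residual |x(t+T)-x(t)| / |x(t)|


@dataclass
class FloquetResult:
    """Monodromy matrix of a limit cycle with its sorted eigenstructure."""

    monodromy: NDArray[np.float64]
    multipliers: NDArray[np.complex128]  # sorted by descending magnitude
    directions: NDArray[np.complex128]  # columns match multipliers
    residual: float = 0.0
    warning: Optional[str] = None


def _check_finite(arr: NDArray, context: str) -> None:
    if not np.all(np.isfinite(arr)) or np.max(np.abs(arr)) > DIVERGENCE_CAP:
        raise DivergedSimulationError(f"simulation diverged during {context}")


# ---------------------------------------------------------------------------
# Complex Ginzburg-Landau equation
# ---------------------------------------------------------------------------


def _etd_phi(z: NDArray[np.complex128]) -> tuple[NDArray, NDArray, NDArray]:
    """exp(z), phi1(z)=(e^z-1)/z and phi2(z)=(e^z-1-z)/z^2, Taylor near 0."""
    E = np.exp(z)
    small = np.abs(z) < 1e-5
    zs = np.where(small, 1.0, z)  # avoid 0/0; overwritten below
    phi1 = (E - 1.0) / zs
    phi2 = (E - 1.0 - z) / zs**2
    phi1 = np.where(small, 1.0 + z / 2.0 + z**2 / 6.0, phi1)
    phi2 = np.where(small, 0.5 + z / 6.0 + z**2 / 24.0, phi2)
    return E, phi1, phi2


def _cgle_random_ic(n_mesh: int, seed: int, sigma: float = 0.1) -> NDArray[np.complex128]:
    """Random initial field: complex Gaussian noise, std ``sigma`` per point."""
    rng = np.random.default_rng(seed)
    return sigma * (rng.standard_normal(n_mesh) + 1j * rng.standard_normal(n_mesh))


def _simulate_cgle_periodic(
    params: CGLEParams,
    W0: NDArray[np.complex128],
    t_burn: float,
    t_sample: float,
    dt_internal: float,
    dt_burn: float,
) -> NDArray[np.complex128]:
    """Pseudospectral ETD2 Runge-Kutta integration; returns sampled snapshots."""
    n = params.n_mesh
    k = 2.0 * np.pi * np.fft.fftfreq(n, d=params.L / n)
    lin = 1.0 - (1.0 + 1j * params.c1) * k**2

    def nonlin(Wh: NDArray) -> NDArray:
        W = np.fft.ifft(Wh)
        return np.fft.fft(-(1.0 - 1j * params.c2) * np.abs(W) ** 2 * W)

    def steps(Wh: NDArray, h: float, n_steps: int, record_every: int = 0):
        E, phi1, phi2 = _etd_phi(h * lin)
        out = []
        for i in range(n_steps):
            Nv = nonlin(Wh)
            a = E * Wh + h * phi1 * Nv
            Wh = a + h * phi2 * (nonlin(a) - Nv)
            if record_every and (i + 1) % record_every == 0:
                out.append(np.fft.ifft(Wh))
        return Wh, out

    Wh = np.fft.fft(W0)
    if t_burn > 0:
        n_burn = int(round(t_burn / dt_burn))
        Wh, _ = steps(Wh, t_burn / n_burn, n_burn)
        _check_finite(np.fft.ifft(Wh), "CGLE burn-in")

    n_out = int(round(t_sample / params.dt_sample))
    sub = max(1, int(round(params.dt_sample / dt_internal)))
    h = params.dt_sample / sub
    snapshots = [np.fft.ifft(Wh)]
    Wh, rec = steps(Wh, h, n_out * sub, record_every=sub)
    snapshots.extend(rec)
    W = np.array(snapshots)
    _check_finite(W, "CGLE sampling")
    return W


def _cgle_noflux_rhs_factory(params: CGLEParams) -> Callable:
    n = params.n_mesh
    dx = params.L / (n - 1)
    a = 1.0 + 1j * params.c1
    b = 1.0 - 1j * params.c2

    def rhs(t: float, y: NDArray) -> NDArray:
        W = y[:n] + 1j * y[n:]
        lap = np.empty_like(W)
        lap[1:-1] = W[2:] - 2.0 * W[1:-1] + W[:-2]
        # Neumann (zero-flux) via mirrored ghost points
        lap[0] = 2.0 * (W[1] - W[0])
        lap[-1] = 2.0 * (W[-2] - W[-1])
        dW = W + a * lap / dx**2 - b * np.abs(W) ** 2 * W
        return np.concatenate([dW.real, dW.imag])

    return rhs


def _simulate_cgle_noflux(
    params: CGLEParams,
    W0: NDArray[np.complex128],
    t_burn: float,
    t_sample: float,
    rtol: float,
    atol: float,
) -> NDArray[np.complex128]:
    """Finite differences in space, stiff multistep (LSODA) integration."""
    n = params.n_mesh
    rhs = _cgle_noflux_rhs_factory(params)
    y = np.concatenate([W0.real, W0.imag])
    if t_burn > 0:
        sol = solve_ivp(rhs, (0.0, t_burn), y, method="LSODA", rtol=rtol, atol=atol)
        if not sol.success:
            raise DivergedSimulationError("CGLE no-flux burn-in failed")
        y = sol.y[:, -1]
        _check_finite(y, "CGLE no-flux burn-in")
    n_out = int(round(t_sample / params.dt_sample))
    t_eval = np.arange(n_out + 1) * params.dt_sample
    sol = solve_ivp(
        rhs, (0.0, t_eval[-1]), y, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise DivergedSimulationError("CGLE no-flux sampling failed")
    _check_finite(sol.y, "CGLE no-flux sampling")
    return (sol.y[:n] + 1j * sol.y[n:]).T  # (timesteps, mesh)


def simulate_cgle(
    params: CGLEParams,
    ic: Optional[NDArray[np.complex128]] = None,
    seed: Optional[int] = None,
    t_burn: float = 1000.0,
    t_sample: float = 20.0,
    dt_internal: float = 0.01,
    dt_burn: float = 0.05,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> TrajectoryEnsemble:
    """Integrate the CGLE and sample the field at ``dt_sample`` after burn-in.

    Parameters
    ----------
    ic
        Complex field of length ``n_mesh``; if omitted, a seeded random field
        (complex Gaussian, std 0.1 per mesh point) is used.
    t_burn, t_sample
        Burn-in length (discarded) and sampled window length.
    dt_internal, dt_burn
        Internal ETD2 step during sampling / burn-in (periodic case only;
        the no-flux case uses an adaptive stiff multistep integrator with
        tolerances ``rtol``/``atol``).
    """
    if ic is None:
        if seed is None:
            raise ValueError("provide either ic or seed")
        W0 = _cgle_random_ic(params.n_mesh, seed)
    else:
        W0 = np.asarray(ic, dtype=complex)
        if W0.shape != (params.n_mesh,):
            raise ValueError("ic length must equal n_mesh")
    if t_burn < 0:
        raise ValueError("burn-in must be nonnegative")

    if params.boundary == "periodic":
        W = _simulate_cgle_periodic(params, W0, t_burn, t_sample, dt_internal, dt_burn)
    else:
        W = _simulate_cgle_noflux(params, W0, t_burn, t_sample, rtol, atol)

    n_out = W.shape[0] - 1
    times = t_burn + np.arange(n_out + 1) * params.dt_sample
    meta = {"system": "cgle", "params": asdict(params), "seed": seed}
    return TrajectoryEnsemble.from_complex(times, W.T, meta)


def cgle_rhs_uniform(W: complex, params: CGLEParams) -> complex:
    """Spatially uniform reduction of the CGLE (the diffusion term vanishes)."""
    return W - (1.0 - 1j * params.c2) * abs(W) ** 2 * W


# ---------------------------------------------------------------------------
# Stuart-Landau ensemble
# ---------------------------------------------------------------------------


def sl_rhs(W: NDArray[np.complex128], params: SLEnsembleParams) -> NDArray[np.complex128]:
    """Complex vector field of the mean-coupled Stuart-Landau ensemble."""
    coupling = params.K * (np.mean(W) - W)
    return (1.0 + 1j * params.omegas) * W - np.abs(W) ** 2 * W + coupling


def _sl_real_rhs_factory(params: SLEnsembleParams) -> Callable:
    n = params.n_osc
    omegas = params.omegas

    def rhs(t: float, y: NDArray) -> NDArray:
        W = y[:n] + 1j * y[n:]
        dW = (1.0 + 1j * omegas) * W - np.abs(W) ** 2 * W + params.K * (np.mean(W) - W)
        return np.concatenate([dW.real, dW.imag])

    return rhs


def simulate_sl_ensemble(
    params: SLEnsembleParams,
    ic: Optional[NDArray[np.complex128]] = None,
    seed: Optional[int] = None,
    t_span: tuple[float, float] = (0.0, 200.0),
    dt_sample: float = 0.05,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> TrajectoryEnsemble:
    """Integrate the Stuart-Landau ensemble, sampling every ``dt_sample``.

    The default initial condition draws each oscillator uniformly from the
    unit square [0, 1] x [0, 1] of the complex plane.
    """
    n = params.n_osc
    if ic is None:
        if seed is None:
            raise ValueError("provide either ic or seed")
        rng = np.random.default_rng(seed)
        W0 = rng.uniform(0.0, 1.0, n) + 1j * rng.uniform(0.0, 1.0, n)
    else:
        W0 = np.asarray(ic, dtype=complex)
        if W0.shape != (n,):
            raise ValueError("ic length must equal n_osc")

    t0, t1 = t_span
    n_out = int(round((t1 - t0) / dt_sample))
    t_eval = t0 + np.arange(n_out + 1) * dt_sample
    rhs = _sl_real_rhs_factory(params)
    y0 = np.concatenate([W0.real, W0.imag])
    sol = solve_ivp(rhs, (t0, t_eval[-1]), y0, method="LSODA", t_eval=t_eval, rtol=rtol, atol=atol)
    if not sol.success:
        raise DivergedSimulationError("Stuart-Landau integration failed")
    _check_finite(sol.y, "Stuart-Landau integration")
    W = (sol.y[:n] + 1j * sol.y[n:])  # (agents, timesteps)
    meta = {"system": "sl", "params": asdict(params), "seed": seed}
    return TrajectoryEnsemble.from_complex(t_eval, W, meta)


def _sl_jacobian_blocks(W: NDArray[np.complex128], params: SLEnsembleParams):
    """Per-oscillator 2x2 Jacobian entries (coupling sum excluded)."""
    a, b = W.real, W.imag
    K, om = params.K, params.omegas
    jaa = 1.0 - 3.0 * a**2 - b**2 - K
    jab = -2.0 * a * b - om
    jba = -2.0 * a * b + om
    jbb = 1.0 - a**2 - 3.0 * b**2 - K
    return jaa, jab, jba, jbb


def sl_jacobian(state: NDArray[np.complex128], params: SLEnsembleParams) -> NDArray[np.float64]:
    """Analytic Jacobian of the real-stacked ([Re W; Im W]) vector field.

    Structure: 2x2 diagonal blocks (the local dynamics minus K) plus a K/N
    rank-one-per-channel coupling contribution from the ensemble mean.
    """
    n = params.n_osc
    state = np.asarray(state, dtype=complex)
    if state.shape != (n,):
        raise ValueError("state length must equal n_osc")
    jaa, jab, jba, jbb = _sl_jacobian_blocks(state, params)
    J = np.zeros((2 * n, 2 * n))
    idx = np.arange(n)
    J[idx, idx] = jaa
    J[idx, idx + n] = jab
    J[idx + n, idx] = jba
    J[idx + n, idx + n] = jbb
    c = params.K / n
    J[:n, :n] += c
    J[n:, n:] += c
    return J


def sl_jacobian_apply(
    state: NDArray[np.complex128], params: SLEnsembleParams, V: NDArray[np.float64]
) -> NDArray[np.float64]:
    """Structured product J(state) @ V in O(N * ncols), without forming J."""
    n = params.n_osc
    jaa, jab, jba, jbb = _sl_jacobian_blocks(np.asarray(state, complex), params)
    Va, Vb = V[:n], V[n:]
    c = params.K / n
    sa = Va.sum(axis=0)
    sb = Vb.sum(axis=0)
    out = np.empty_like(V)
    out[:n] = jaa[:, None] * Va + jab[:, None] * Vb + c * sa
    out[n:] = jba[:, None] * Va + jbb[:, None] * Vb + c * sb
    return out


# ---------------------------------------------------------------------------
# Limit cycles and Floquet analysis
# ---------------------------------------------------------------------------


def _flat_states(traj: TrajectoryEnsemble) -> NDArray[np.float64]:
    """(timesteps, agents*channels) view of the trajectory."""
    return traj.states.transpose(1, 0, 2).reshape(traj.times.size, -1)


def find_limit_cycle(
    traj: TrajectoryEnsemble,
    tol_per: float = TOL_PERIOD,
    amplitude_tol: float = 1e-4,
) -> LimitCycle:
    """Detect a periodic orbit in a settled trajectory.

    The period is first estimated from successive upward zero crossings of
    the (mean-removed) ensemble-mean observable, then refined by minimizing
    the recurrence residual ||x(t0 + T) - x(t0)|| over T with cubic
    interpolation in time. Raises :class:`NoCycleError` when the trajectory
    has collapsed to a fixed point or shows no recurrence.
    """
    flat = _flat_states(traj)
    t = traj.times
    s = flat.mean(axis=1)
    s = s - s.mean()
    if s.std() < amplitude_tol and np.abs(np.diff(flat, axis=0)).max() < amplitude_tol:
        raise NoCycleError("trajectory has settled to a fixed point")

    crossings = np.nonzero((s[:-1] < 0) & (s[1:] >= 0))[0]
    if crossings.size < 2:
        raise NoCycleError("no oscillation detected in the mean observable")
    # linear-interpolation refinement of the crossing times
    tc = t[crossings] + (t[crossings + 1] - t[crossings]) * (-s[crossings]) / (
        s[crossings + 1] - s[crossings]
    )
    T0 = float(np.mean(np.diff(tc)))

    spline = CubicSpline(t, flat, axis=0)
    t_anchor = float(t[0])
    x0 = spline(t_anchor)
    nrm = np.linalg.norm(x0)

    def residual(T: float) -> float:
        return np.linalg.norm(spline(t_anchor + T) - x0)

    lo, hi = 0.8 * T0, 1.2 * T0
    if t_anchor + hi > t[-1]:
        raise NoCycleError("trajectory shorter than one estimated period")
    res = minimize_scalar(residual, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-12})
    T = float(res.x)
    rel = float(res.fun / nrm) if nrm > 0 else float(res.fun)
    if rel > np.sqrt(tol_per):
        # loose sanity bound; the strict tol is reported, not enforced
        raise NoCycleError(f"recurrence residual {rel:.2e} too large for a cycle")

    # one-period samples on the original grid
    mask = (t >= t_anchor) & (t <= t_anchor + T + traj.dt)
    samples = TrajectoryEnsemble(
        times=t[mask], states=traj.states[:, mask, :], meta=dict(traj.meta)
    )
    n_ch = traj.n_channels
    anchor = x0.reshape(traj.n_agents, n_ch)
    return LimitCycle(period=T, samples=samples, anchor=anchor, residual=rel)


def compute_monodromy(
    lc: LimitCycle,
    params: SLEnsembleParams,
    n_steps: int = 1024,
    tol_per: float = TOL_PERIOD,
) -> FloquetResult:
    """Integrate the variational equation dV/dt = J(x(t)) V over one period.

    V(0) is the identity; the reference orbit x(t) is interpolated from the
    limit-cycle samples with a cubic spline. The Jacobian is applied in its
    structured form (2x2 blocks plus mean-field coupling), which keeps the
    cost at O(N^2) per step. Classic fixed-step RK4 is used in time.
    """
    n = params.n_osc
    t = lc.samples.times
    flat = _flat_states(lc.samples)
    spline = CubicSpline(t - t[0], flat, axis=0)

    def state_at(tau: float) -> NDArray[np.complex128]:
        y = spline(tau).reshape(n, -1)  # flat states are agent-major
        return y[:, 0] + 1j * y[:, 1]

    h = lc.period / n_steps
    V = np.eye(2 * n)
    for i in range(n_steps):
        tau = i * h
        W1 = state_at(tau)
        W2 = state_at(tau + 0.5 * h)
        W3 = state_at(tau + h)
        k1 = sl_jacobian_apply(W1, params, V)
        k2 = sl_jacobian_apply(W2, params, V + 0.5 * h * k1)
        k3 = sl_jacobian_apply(W2, params, V + 0.5 * h * k2)
        k4 = sl_jacobian_apply(W3, params, V + h * k3)
        V = V + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)

    vals, vecs = np.linalg.eig(V)
    order = np.argsort(-np.abs(vals))
    vals, vecs = vals[order], vecs[:, order]
    resid = float(np.linalg.norm(V @ vecs[:, 0] - vals[0] * vecs[:, 0]))
    warning = None
    if lc.residual > tol_per:
        warning = f"limit-cycle recurrence residual {lc.residual:.2e} exceeds tol {tol_per:.0e}"
    return FloquetResult(
        monodromy=V, multipliers=vals, directions=vecs, residual=resid, warning=warning
    )


def propagate_floquet_direction(
    lc: LimitCycle,
    params: SLEnsembleParams,
    v0: NDArray[np.float64],
    taus: Sequence[float],
    n_steps_per_unit: int = 200,
) -> NDArray[np.float64]:
    """Transport a Floquet eigendirection along the cycle.

    Integrating the variational equation maps the monodromy eigendirection at
    the anchor into the corresponding eigendirection at phase tau; each
    transported vector is re-normalized. Returns an array (len(taus), 2N).
    """
    n = params.n_osc
    t = lc.samples.times
    flat = _flat_states(lc.samples)
    spline = CubicSpline(t - t[0], flat, axis=0)

    def state_at(tau: float):
        y = spline(tau).reshape(n, -1)  # flat states are agent-major
        return y[:, 0] + 1j * y[:, 1]

    taus = np.asarray(taus, float)
    if np.any(np.diff(taus) < 0) or taus[0] < 0:
        raise ValueError("taus must be nondecreasing and nonnegative")
    out = np.empty((taus.size, 2 * n))
    v = np.asarray(v0, float).copy()
    tau_now = 0.0
    for j, tau in enumerate(taus):
        if tau > tau_now:
            n_steps = max(1, int(np.ceil((tau - tau_now) * n_steps_per_unit)))
            h = (tau - tau_now) / n_steps
            for i in range(n_steps):
                s = tau_now + i * h
                W1, W2, W3 = state_at(s), state_at(s + 0.5 * h), state_at(s + h)
                k1 = sl_jacobian_apply(W1, params, v[:, None])[:, 0]
                k2 = sl_jacobian_apply(W2, params, (v + 0.5 * h * k1)[:, None])[:, 0]
                k3 = sl_jacobian_apply(W2, params, (v + 0.5 * h * k2)[:, None])[:, 0]
                k4 = sl_jacobian_apply(W3, params, (v + h * k3)[:, None])[:, 0]
                v = v + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            tau_now = tau
        out[j] = v / np.linalg.norm(v)
    return out


# ---------------------------------------------------------------------------
# Chung-Lu random graphs
# ---------------------------------------------------------------------------


def chung_lu_weights(n: int, p: float, r: float) -> NDArray[np.float64]:
    """Expected-degree weights w_k = p N (k/N)^r for k = 1..N."""
    k = np.arange(1, n + 1)
    return p * n * (k / n) ** r


def chung_lu_edge_probabilities(n: int, p: float, r: float) -> NDArray[np.float64]:
    """Matrix of pairwise edge probabilities min(w_k w_j / sum(w), 1)."""
    w = chung_lu_weights(n, p, r)
    P = np.minimum(np.outer(w, w) / w.sum(), 1.0)
    np.fill_diagonal(P, 0.0)
    return P


def build_chung_lu_adjacency(n: int, p: float, r: float, seed: int = 0) -> NDArray[np.int8]:
    """Sample a symmetric 0/1 Chung-Lu adjacency matrix with zero diagonal."""
    if not (0.0 <= p <= 1.0) or r < 0:
        raise ValueError("require 0 <= p <= 1 and r >= 0")
    P = chung_lu_edge_probabilities(n, p, r)
    rng = np.random.default_rng(seed)
    U = rng.random((n, n))
    upper = np.triu(U < P, k=1)
    A = (upper | upper.T).astype(np.int8)
    return A


# ---------------------------------------------------------------------------
# Hodgkin-Huxley network
# ---------------------------------------------------------------------------


def hh_m(V):
    """Sodium activation gate (instantaneous sigmoid)."""
    return 1.0 / (1.0 + np.exp(-(V + 37.0) / 6.0))


def hh_hinf(V):
    return 1.0 / (1.0 + np.exp((V + 44.0) / 6.0))


def hh_tau(V, eps: float = 0.1):
    return 1.0 / (eps * np.cosh((V + 40.0) / 5.0))


def hh_s(V):
    """Synaptic activation sigmoid."""
    return 1.0 / (1.0 + np.exp(-(V + 40.0) / 5.0))


def _hh_rhs_factory(params: HHNetworkParams) -> Callable:
    n = params.n_neurons
    A = params.adjacency.astype(float)
    I_app = params.I_app
    C, eps = params.C_mem, params.eps_hh
    g_Na, g_l, g_syn = params.g_Na, params.g_l, params.g_syn
    V_Na, V_l, V_syn = params.V_Na, params.V_l, params.V_syn

    def rhs(t: float, y: NDArray) -> NDArray:
        V, h = y[:n], y[n:]
        I_syn = g_syn * (V_syn - V) / n * (A @ hh_s(V))
        dV = (-g_Na * hh_m(V) * h * (V - V_Na) - g_l * (V - V_l) + I_syn + I_app) / C
        dh = (hh_hinf(V) - h) * eps * np.cosh((V + 40.0) / 5.0)
        return np.concatenate([dV, dh])

    return rhs


def simulate_hh_network(
    params: HHNetworkParams,
    t_span: tuple[float, float] = (0.0, 140.0),
    t_min: float = 120.0,
    dt_sample: float = 2e-3,
    ic: Optional[NDArray[np.float64]] = None,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> TrajectoryEnsemble:
    """Integrate the neuron network with an embedded Runge-Kutta 5(4) method.

    Samples (V_k, h_k) every ``dt_sample`` on [t_min, t_span[1]]; the default
    initial condition is V_k = -60, h_k = 0 for all neurons.
    """
    params.validate()
    n = params.n_neurons
    if ic is None:
        y0 = np.concatenate([np.full(n, -60.0), np.zeros(n)])
    else:
        y0 = np.asarray(ic, float).reshape(2 * n)
    rhs = _hh_rhs_factory(params)
    t0, t1 = t_span
    if t_min > t0:
        sol = solve_ivp(rhs, (t0, t_min), y0, method="RK45", rtol=rtol, atol=atol)
        if not sol.success:
            raise DivergedSimulationError("HH burn-in failed")
        y0 = sol.y[:, -1]
    n_out = int(round((t1 - t_min) / dt_sample))
    t_eval = t_min + np.arange(n_out + 1) * dt_sample
    sol = solve_ivp(
        rhs, (t_min, t_eval[-1]), y0, method="RK45", t_eval=t_eval, rtol=rtol, atol=atol
    )
    if not sol.success:
        raise DivergedSimulationError("HH sampling failed")
    _check_finite(sol.y, "HH sampling")
    states = np.stack([sol.y[:n].astype(np.float32), sol.y[n:].astype(np.float32)], axis=-1)
    meta = {
        "system": "hh",
        "params": {
            k: v for k, v in asdict(params).items() if k not in ("I_app", "adjacency")
        },
    }
    return TrajectoryEnsemble(times=t_eval, states=states, meta=meta)


def rescale_hh(traj: TrajectoryEnsemble) -> TrajectoryEnsemble:
    """Affinely rescale (V, h) -> ((V+37)/30, (h-0.42)/0.2).

    Both channels become approximately mean-centered and share one scale.
    The transform is exactly invertible by :func:`unscale_hh`.
    """
    V = (traj.states[:, :, 0] + HH_V_SHIFT) / HH_V_SCALE
    h = (traj.states[:, :, 1] - HH_H_SHIFT) / HH_H_SCALE
    meta = dict(traj.meta)
    meta["rescaled"] = True
    return TrajectoryEnsemble(traj.times, np.stack([V, h], axis=-1), meta)


def unscale_hh(traj: TrajectoryEnsemble) -> TrajectoryEnsemble:
    """Exact inverse of :func:`rescale_hh`."""
    V = traj.states[:, :, 0] * HH_V_SCALE - HH_V_SHIFT
    h = traj.states[:, :, 1] * HH_H_SCALE + HH_H_SHIFT
    meta = dict(traj.meta)
    meta.pop("rescaled", None)
    return TrajectoryEnsemble(traj.times, np.stack([V, h], axis=-1), meta)
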