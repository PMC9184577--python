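"""Map scattered per-agent data onto regular grids in emergent space.

Agents land at arbitrary positions along the learned coordinate(s), but the
finite-difference features of the PDE require equispaced samples: 1D
coordinates are resampled with cubic splines (periodically closed on a
circular coordinate), 2D coordinates with local weighted least-squares
polynomial fits of total degree <= 2 evaluated on a rectangle inside the
point cloud.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from numpy.typing import NDArray
from scipy.interpolate import CubicSpline
from scipy.sparse import csr_matrix
from scipy.spatial import cKDTree

__all__ = [
    "EmergentGrid",
    "GriddedField",
    "resample_line",
    "resample_rectangle",
    "build_rectangle_grid",
    "local_quadratic_smoother",
]


@dataclass
class EmergentGrid:
    """A uniform 1D interval grid or 2D rectangular grid in emergent space."""

    axes: list[NDArray[np.float64]]  # one sorted uniform coordinate array per dim
    periodic: tuple[bool, ...] = (False,)

    def __post_init__(self) -> None:
        self.axes = [np.asarray(a, float) for a in self.axes]
        for a in self.axes:
            d = np.diff(a)
            if a.size < 2 or not np.allclose(d, d[0], rtol=1e-10):
                raise ValueError("grid axes must be uniform with >= 2 points")
        if len(self.periodic) != len(self.axes):
            raise ValueError("periodic flags must match dimensions")

    @property
    def dims(self) -> int:
        return len(self.axes)

    @property
    def spacing(self) -> tuple[float, ...]:
        return tuple(float(a[1] - a[0]) for a in self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(a.size for a in self.axes)

    @classmethod
    def line(cls, lo: float, hi: float, n: int, periodic: bool = False) -> "EmergentGrid":
        pts = np.linspace(lo, hi, n, endpoint=not periodic)
        return cls(axes=[pts], periodic=(periodic,))


@dataclass
class GriddedField:
    """Field snapshots on an emergent-space grid, with optional d/dt targets.

    ``values`` has shape (timesteps, *grid_shape, channels); ``dWdt`` matches
    ``values`` with one fewer timestep (forward differences drop the last
    snapshot).
    """

    grid: EmergentGrid
    values: NDArray[np.float64]
    times: Optional[NDArray[np.float64]] = None
    dWdt: Optional[NDArray[np.float64]] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expect = self.grid.shape
        if tuple(self.values.shape[1 : 1 + self.grid.dims]) != expect:
            raise ValueError("values shape inconsistent with grid")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("NaN/Inf inside the gridded field")
        if self.dWdt is not None and self.dWdt.shape[1:] != self.values.shape[1:]:
            raise ValueError("dWdt shape inconsistent with values")

    @property
    def n_channels(self) -> int:
        return self.values.shape[-1]

    def with_time_derivative(self, dt: float) -> "GriddedField":
        """Attach forward-difference targets; drops nothing from ``values``."""
        d = np.diff(self.values.astype(float), axis=0) / dt
        return GriddedField(self.grid, self.values, self.times, d, dict(self.meta))


def resample_line(
    coords: NDArray[np.float64],
    snapshots: NDArray[np.float64],
    grid: EmergentGrid,
    periodic: Optional[bool] = None,
    method: str = "cubic",
) -> GriddedField:
    """Spline resampling of scattered 1D data onto a uniform grid.

    Parameters
    ----------
    coords
        Per-agent emergent coordinate, shape (agents,). Exact ties are an
        error.
    snapshots
        Agent values, shape (agents, timesteps, channels) (a trajectory's
        ``states``) or (agents, channels) for a single snapshot.
    periodic
        Close the spline over a 2*pi period (circular coordinate). Defaults
        to the grid's flag.
    method
        ``cubic`` (interpolating cubic spline, not-a-knot ends) or ``pchip``
        (shape-preserving monotone cubic). Agents can cluster very tightly
        along the emergent coordinate; an interpolating spline may then
        oscillate wildly between near-duplicate knots, and the monotone
        variant is the robust choice. Periodic closure always uses the
        cubic spline.
    """
    coords = np.asarray(coords, float)
    single = snapshots.ndim == 2
    vals = snapshots[:, None, :] if single else snapshots
    if coords.ndim != 1 or coords.size != vals.shape[0]:
        raise ValueError("coords must be one value per agent")
    if periodic is None:
        periodic = grid.periodic[0]
    order = np.argsort(coords)
    x = coords[order]
    if np.any(np.diff(x) <= 0):
        raise ValueError("duplicate emergent coordinates")
    y = vals[order].astype(float)  # (agents, T, ch)
    gx = grid.axes[0]
    if periodic:
        xp = np.concatenate([x, [x[0] + 2.0 * np.pi]])
        yp = np.concatenate([y, y[:1]], axis=0)
        spline = CubicSpline(xp, yp, axis=0, bc_type="periodic")
        query = x[0] + np.mod(gx - x[0], 2.0 * np.pi)
        out = spline(query)
    else:
        if gx[0] < x[0] - 1e-12 or gx[-1] > x[-1] + 1e-12:
            raise ValueError("grid extends outside the data support")
        if method == "pchip":
            from scipy.interpolate import PchipInterpolator

            spline = PchipInterpolator(x, y, axis=0)
        elif method == "cubic":
            spline = CubicSpline(x, y, axis=0)  # not-a-knot ends
        else:
            raise ValueError(f"unknown method {method!r}")
        out = spline(np.clip(gx, x[0], x[-1]))
    out = out.transpose(1, 0, 2)  # (T, grid, ch); single snapshots give T=1
    return GriddedField(grid, out)


def build_rectangle_grid(
    phi1: NDArray[np.float64],
    phi2: NDArray[np.float64],
    n: int = 64,
    fraction: float = 0.7,
) -> EmergentGrid:
    """Rectangle covering the central ``fraction`` of the embedding's bounding
    box per axis, with ``n`` points per direction."""
    axes = []
    for phi in (phi1, phi2):
        lo, hi = float(np.min(phi)), float(np.max(phi))
        c, half = 0.5 * (lo + hi), 0.5 * (hi - lo) * fraction
        axes.append(np.linspace(c - half, c + half, n))
    return EmergentGrid(axes=axes, periodic=(False, False))


def local_quadratic_smoother(
    phi1: NDArray[np.float64],
    phi2: NDArray[np.float64],
    grid: EmergentGrid,
    poly_order: int = 2,
    bandwidth_factor: float = 2.0,
    global_fit: bool = False,
) -> csr_matrix:
    """Linear map from scattered agent values to grid-node values.

    At each node a weighted least-squares polynomial of total degree
    ``poly_order`` is fitted (Gaussian weights, bandwidth ``bandwidth_factor``
    grid spacings) and evaluated at the node. Because the fit is linear in
    the data, the whole operation collapses into one sparse matrix that can
    be reused across snapshots and channels. ``global_fit`` uses a single
    unweighted polynomial over all agents instead.
    """
    pts = np.stack([np.asarray(phi1, float), np.asarray(phi2, float)], axis=1)
    n_agents = pts.shape[0]
    g1, g2 = np.meshgrid(grid.axes[0], grid.axes[1], indexing="ij")
    nodes = np.stack([g1.ravel(), g2.ravel()], axis=1)
    powers = [(i, j) for i in range(poly_order + 1) for j in range(poly_order + 1 - i)]
    n_coef = len(powers)

    def design(xy: NDArray) -> NDArray:
        return np.stack([xy[:, 0] ** i * xy[:, 1] ** j for i, j in powers], axis=1)

    if global_fit:
        X = design(pts)
        G = X.T @ X
        M = design(nodes) @ np.linalg.solve(G, X.T)  # (nodes, agents), dense
        return csr_matrix(M)

    sigma = bandwidth_factor * max(grid.spacing)
    tree = cKDTree(pts)
    rows, cols, data = [], [], []
    cutoff = 3.0 * sigma
    for node_id, node in enumerate(nodes):
        idx = tree.query_ball_point(node, cutoff)
        if len(idx) < n_coef:
            idx = list(tree.query(node, k=max(n_coef * 3, 12))[1])
        idx = np.asarray(idx)
        local = pts[idx] - node
        w = np.exp(-np.sum(local**2, axis=1) / (2.0 * sigma**2))
        X = design(local)
        Xw = X * w[:, None]
        G = Xw.T @ X
        if np.linalg.cond(G) > 1e12:
            raise np.linalg.LinAlgError(
                f"rank-deficient local fit at grid node {node_id}"
            )
        # value at the node = coefficient of the constant term
        e0 = np.zeros(n_coef)
        e0[powers.index((0, 0))] = 1.0
        smoother_row = np.linalg.solve(G, e0) @ Xw.T
        rows.extend([node_id] * idx.size)
        cols.extend(idx.tolist())
        data.extend(smoother_row.tolist())
    return csr_matrix((data, (rows, cols)), shape=(nodes.shape[0], n_agents))


def resample_rectangle(
    phi1: NDArray[np.float64],
    phi2: NDArray[np.float64],
    values: NDArray[np.float64],
    grid: EmergentGrid,
    poly_order: int = 2,
    bandwidth_factor: float = 2.0,
    global_fit: bool = False,
    smoother: Optional[csr_matrix] = None,
) -> GriddedField:
    """Fit scattered 2D data with local polynomials and sample the grid.

    ``values`` is (agents, timesteps, channels) or (agents, channels); pass a
    precomputed ``smoother`` to amortize the fit across many calls.
    """
    single = values.ndim == 2
    vals = values[:, None, :] if single else values
    n_agents, n_t, n_ch = vals.shape
    if smoother is None:
        smoother = local_quadratic_smoother(
            phi1, phi2, grid, poly_order, bandwidth_factor, global_fit
        )
    flat = vals.reshape(n_agents, n_t * n_ch).astype(float)
    out = smoother @ flat  # (nodes, T*ch)
    n1, n2 = grid.shape
    out = out.reshape(n1, n2, n_t, n_ch).transpose(2, 0, 1, 3)
    return GriddedField(grid, out if not single else out[:1])
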