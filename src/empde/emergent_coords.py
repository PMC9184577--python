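"""Diffusion-maps embedding of agent time series.

Each agent's full (real-channel, concatenated) time series is one data point.
A Gaussian kernel over pairwise Euclidean distances is row-normalized into a
Markov transition matrix whose leading independent eigenvectors supply the
emergent spatial coordinate(s): eigenvectors that are harmonics of earlier
ones parametrize no new direction and are rejected, either manually or with
a local-linear-regression residual test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from numpy.typing import NDArray
from scipy.linalg import eigh
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "DiffusionResult",
    "EmergentCoordinate",
    "median_kernel_scale",
    "nn_median_kernel_scale",
    "nn_max_kernel_scale",
    "compute_kernel_matrix",
    "diffusion_eigendecomposition",
    "select_independent_modes",
    "circular_coordinate",
    "scale_modes",
    "embed_features",
    "ensemble_feature_matrix",
]


@dataclass
class DiffusionResult:
    """Eigenstructure of the diffusion (row-stochastic) matrix.

    ``eigenvectors`` are columns ordered by descending eigenvalue; index 0 is
    the trivial constant mode (eigenvalue 1). ``selected`` holds indices of
    the independent (non-harmonic) modes; ``scaled_modes`` are those modes
    affinely mapped onto [-1, 1].
    """

    kernel_scale: float
    eigenvalues: NDArray[np.float64]
    eigenvectors: NDArray[np.float64]  # (agents, modes)
    selected: Optional[list[int]] = None
    scaled_modes: Optional[NDArray[np.float64]] = None
    scaling: Optional[list[tuple[float, float]]] = None  # (min, max) per mode
    llr_residuals: Optional[NDArray[np.float64]] = None


@dataclass
class EmergentCoordinate:
    """A per-agent emergent coordinate with its orientation convention."""

    kind: str  # "linear_mode" | "circular_angle" | "planar_pair"
    values: NDArray[np.float64]
    orientation_sign: int = 1

    def __post_init__(self) -> None:
        if self.kind == "circular_angle":
            v = np.asarray(self.values)
            if np.any(v < -np.pi) or np.any(v >= np.pi):
                raise ValueError("circular angles must lie in [-pi, pi)")


def ensemble_feature_matrix(trajectories: Sequence) -> NDArray[np.float64]:
    """Concatenate each agent's time series into one feature row.

    Accepts a list of :class:`~empde.simulators.TrajectoryEnsemble` sharing
    the agent count; channels and trajectories are concatenated along the
    feature axis, so row k is the full observed history of agent k.
    """
    rows = []
    for traj in trajectories:
        rows.append(traj.states.reshape(traj.n_agents, -1))
    return np.concatenate(rows, axis=1).astype(float)


def median_kernel_scale(features: NDArray[np.float64]) -> float:
    """Median of all squared pairwise Euclidean distances."""
    d2 = pdist(features, "sqeuclidean")
    return float(np.median(d2))


def nn_median_kernel_scale(features: NDArray[np.float64]) -> float:
    """Median of per-point nearest-neighbor squared distances.

    A local kernel scale: with eps at this magnitude only genuinely close
    time series carry kernel weight, which is what lets the embedding trace
    out the data manifold rather than its coarse diameter.
    """
    D2 = squareform(pdist(features, "sqeuclidean"))
    np.fill_diagonal(D2, np.inf)
    return float(np.median(D2.min(axis=1)))


def nn_max_kernel_scale(features: NDArray[np.float64]) -> float:
    """Largest per-point nearest-neighbor squared distance.

    The smallest scale at which every point keeps at least e^-1 kernel
    weight to some neighbor, i.e. the kernel graph stays connected. The
    right choice when the data density varies strongly along the manifold
    (heterogeneous oscillator ensembles); for uniformly dense manifolds the
    tighter :func:`nn_median_kernel_scale` resolves more structure.
    """
    D2 = squareform(pdist(features, "sqeuclidean"))
    np.fill_diagonal(D2, np.inf)
    return float(D2.min(axis=1).max())


def compute_kernel_matrix(
    series_matrix: NDArray[np.float64], eps: Union[float, str]
) -> NDArray[np.float64]:
    """Gaussian kernel K_ij = exp(-||x_i - x_j||^2 / eps) between agents.

    ``eps`` may be a positive number or ``"median"`` (median of the squared
    pairwise distances).
    """
    X = np.asarray(series_matrix, float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite features")
    d2 = squareform(pdist(X, "sqeuclidean"))
    if eps == "median":
        eps = float(np.median(d2[np.triu_indices_from(d2, k=1)]))
    elif eps == "nn_median":
        eps = nn_median_kernel_scale(X)
    elif eps == "nn_max":
        eps = nn_max_kernel_scale(X)
    if not (isinstance(eps, (int, float)) and eps > 0):
        raise ValueError("eps must be positive or one of 'median', 'nn_median', 'nn_max'")
    K = np.exp(-d2 / eps)
    # exact symmetry and unit diagonal, robust to rounding
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K


def _fix_sign(vec: NDArray[np.float64]) -> NDArray[np.float64]:
    """Reproducible sign convention: largest-|loading| entry is positive."""
    i = int(np.argmax(np.abs(vec)))
    return vec if vec[i] >= 0 else -vec


def diffusion_eigendecomposition(
    kernel: NDArray[np.float64],
    n_modes: int = 12,
    kernel_scale: float = np.nan,
) -> DiffusionResult:
    """Leading eigenpairs of the row-normalized kernel (diffusion) matrix.

    Computed through the symmetric conjugate D^{-1/2} K D^{-1/2} for
    numerical stability, so the spectrum is real; eigenvalues are sorted
    descending and the trivial constant mode is kept at index 0.
    """
    K = np.asarray(kernel, float)
    if np.any(K < 0):
        raise ValueError("kernel must be nonnegative")
    d = K.sum(axis=1)
    if np.any(d <= 0):
        raise ValueError("kernel has a zero row sum")
    inv_sqrt = 1.0 / np.sqrt(d)
    S = inv_sqrt[:, None] * K * inv_sqrt[None, :]
    n = K.shape[0]
    n_modes = min(n_modes, n)
    vals, vecs = eigh(S, subset_by_index=(n - n_modes, n - 1))
    vals, vecs = vals[::-1], vecs[:, ::-1]
    # map symmetric eigenvectors back to right eigenvectors of D^-1 K
    phi = inv_sqrt[:, None] * vecs
    phi /= np.linalg.norm(phi, axis=0, keepdims=True)
    phi = np.apply_along_axis(_fix_sign, 0, phi)
    return DiffusionResult(kernel_scale=kernel_scale, eigenvalues=vals, eigenvectors=phi)


def _llr_residuals(
    phi: NDArray[np.float64], n_check: int, scale_factor: float = 1.0 / 3.0
) -> NDArray[np.float64]:
    """Local-linear-regression residuals r_k of each nontrivial eigenvector.

    Mode k is regressed on modes 1..k-1 with a Gaussian-weighted local linear
    model; a residual near one marks a new independent direction, a residual
    near zero a harmonic of earlier modes. The first nontrivial mode has
    r = 1 by definition.
    """
    res = np.ones(n_check)
    n = phi.shape[0]
    for k in range(2, n_check + 1):
        prev = phi[:, 1:k]
        target = phi[:, k]
        d2 = squareform(pdist(prev, "sqeuclidean"))
        eps = np.median(d2[np.triu_indices(n, k=1)]) * scale_factor
        W = np.exp(-d2 / max(eps, 1e-300))
        np.fill_diagonal(W, 0.0)  # leave-one-out
        X = np.concatenate([np.ones((n, 1)), prev], axis=1)
        pred = np.empty(n)
        for i in range(n):
            w = W[i]
            Xw = X * w[:, None]
            G = Xw.T @ X
            b = Xw.T @ target
            coef = np.linalg.lstsq(G, b, rcond=None)[0]
            pred[i] = X[i] @ coef
        res[k - 1] = np.sqrt(np.sum((target - pred) ** 2) / np.sum(target**2))
    return res


def select_independent_modes(
    dr: DiffusionResult,
    method: str = "local_linear_regression",
    params: Optional[dict] = None,
) -> list[int]:
    """Indices of eigenvectors that parametrize new directions.

    ``manual`` returns the configured indices unchanged; the default
    local-linear-regression test examines the first ten nontrivial modes and
    keeps those whose residual exceeds ``threshold`` (default 0.5).
    """
    params = params or {}
    if method == "manual":
        selected = list(params["indices"])
    elif method == "local_linear_regression":
        n_check = min(params.get("n_check", 10), dr.eigenvectors.shape[1] - 1)
        if dr.eigenvectors.shape[1] < 11:
            n_check = dr.eigenvectors.shape[1] - 1
        threshold = params.get("threshold", 0.5)
        max_modes = params.get("max_modes")
        res = _llr_residuals(dr.eigenvectors, n_check)
        dr.llr_residuals = res
        selected = [k + 1 for k in range(n_check) if res[k] > threshold]
        if max_modes is not None:
            selected = selected[:max_modes]
    else:
        raise ValueError(f"unknown selection method {method!r}")
    if not selected:
        raise ValueError("empty mode selection")
    dr.selected = selected
    return selected


def circular_coordinate(
    phi1: NDArray[np.float64], phi2: NDArray[np.float64], orientation_sign: int = 1
) -> EmergentCoordinate:
    """Angle coordinate on the circle spanned by two diffusion modes.

    Returns angles in [-pi, pi); ``orientation_sign=-1`` reflects the second
    mode, flipping the traversal direction while preserving neighbor order.
    """
    phi1 = np.asarray(phi1, float)
    phi2 = np.asarray(phi2, float)
    r = np.hypot(phi1, phi2)
    if np.any(r < 1e-12 * r.max()):
        raise ValueError("points at the origin have no angle")
    angles = np.arctan2(orientation_sign * phi2, phi1)
    angles = np.where(angles >= np.pi, angles - 2 * np.pi, angles)
    return EmergentCoordinate(
        kind="circular_angle", values=angles, orientation_sign=orientation_sign
    )


def scale_modes(dr: DiffusionResult) -> DiffusionResult:
    """Affinely map each selected mode onto [-1, 1], recording the mapping.

    Idempotent: a mode already spanning [-1, 1] is left unchanged.
    """
    if dr.selected is None:
        raise ValueError("run select_independent_modes first")
    scaled, mapping = [], []
    for idx in dr.selected:
        v = dr.eigenvectors[:, idx]
        lo, hi = float(v.min()), float(v.max())
        if hi - lo < 1e-15:
            raise ValueError(f"mode {idx} is constant and cannot be scaled")
        scaled.append(2.0 * (v - lo) / (hi - lo) - 1.0)
        mapping.append((lo, hi))
    dr.scaled_modes = np.stack(scaled, axis=1)
    dr.scaling = mapping
    return dr


def embed_features(
    features: NDArray[np.float64],
    eps: Union[float, str] = "median",
    n_modes: int = 12,
    selection: str = "local_linear_regression",
    selection_params: Optional[dict] = None,
) -> DiffusionResult:
    """Full embedding convenience: kernel, spectrum, selection, scaling."""
    if eps == "median":
        eps_val = median_kernel_scale(features)
    elif eps == "nn_median":
        eps_val = nn_median_kernel_scale(features)
    elif eps == "nn_max":
        eps_val = nn_max_kernel_scale(features)
    else:
        eps_val = float(eps)
    K = compute_kernel_matrix(features, eps_val)
    dr = diffusion_eigendecomposition(K, n_modes=n_modes, kernel_scale=eps_val)
    select_independent_modes(dr, method=selection, params=selection_params)
    return scale_modes(dr)
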