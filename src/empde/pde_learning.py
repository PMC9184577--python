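"""Supervised learning of the PDE right-hand side in emergent space.

The model is a fully connected network f mapping the local field value and
its first few emergent-space derivatives (computed with maximal-accuracy
centered finite-difference stencils) to the local time derivative:

    dW/dt (x, t) ~ f(W, dW/dx, d2W/dx2, ...; gamma)

Complex fields enter as two real channels; in 2D the derivative stack holds
per-axis derivatives without mixed terms. Training minimizes the mean-squared
error against forward-difference time derivatives with Adam and a
reduce-on-plateau learning-rate schedule. The network, backpropagation and
optimizer are implemented here directly on numpy arrays, which keeps training
bit-reproducible for a given seed on one device.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numpy.typing import NDArray
from scipy.ndimage import correlate1d

__all__ = [
    "StencilSpec",
    "PDEModelSpec",
    "TrainConfig",
    "MLP",
    "fd_coefficients",
    "spatial_derivative_stack",
    "assemble_features",
    "train_pde_model",
    "predict_rhs",
]


# ---------------------------------------------------------------------------
# Finite-difference stencils
# ---------------------------------------------------------------------------


@dataclass
class StencilSpec:
    """Centered finite-difference stencil for one derivative order."""

    deriv_order: int
    length: int
    coefficients: NDArray[np.float64]  # includes the h^-n scaling
    accuracy_order: int
    spacing: float


def fd_coefficients(n: int, l: int, h: float = 1.0) -> StencilSpec:
    """Maximal-accuracy centered stencil of length ``l`` for the n-th derivative.

    Solves the Taylor-moment system sum_j c_j o_j^m / m! = delta_{mn} for
    m = 0..l-1 over the symmetric offsets o_j; coefficients scale as h^-n.
    """
    if l % 2 == 0:
        raise ValueError("stencil length must be odd")
    if n >= l:
        raise ValueError("derivative order must be below the stencil length")
    offsets = np.arange(l) - l // 2
    A = np.array(
        [offsets.astype(float) ** m / math.factorial(m) for m in range(l)]
    )
    b = np.zeros(l)
    b[n] = 1.0
    c = np.linalg.solve(A, b)
    # achieved order: first non-annihilated Taylor moment beyond n
    q = 1
    while True:
        m = n + q
        moment = np.sum(c * offsets.astype(float) ** m) / math.factorial(m)
        if abs(moment) > 1e-8:
            break
        q += 1
        if q > 2 * l:
            break
    return StencilSpec(
        deriv_order=n,
        length=l,
        coefficients=c / h**n,
        accuracy_order=q,
        spacing=h,
    )


def spatial_derivative_stack(
    values: NDArray[np.float64],
    n_derivs: int,
    l: int,
    spacing,
    boundary: str = "periodic",
) -> NDArray[np.float64]:
    """Derivative features 1..n_derivs per channel (per axis in 2D, no mixed).

    Parameters
    ----------
    values
        (..., n_grid, channels) for 1D or (..., n1, n2, channels) for 2D;
        leading axes (e.g. time) are broadcast over.
    spacing
        Grid spacing, a scalar (1D) or a pair (2D).
    boundary
        ``periodic`` wraps the stencil; ``interior_only`` returns features on
        the full grid computed with wrap-free one-sided *truncation avoided*:
        values outside the valid interior are filled by nearest-edge mode and
        must be discarded by the caller via :func:`interior_slice`.

    Returns the feature array with channels ordered as
    (channel0, channel0', channel0'', ..., channel1, channel1', ...).
    """
    if boundary not in ("periodic", "interior_only"):
        raise ValueError(f"unknown boundary mode {boundary!r}")
    vals = np.asarray(values, float)
    two_d = np.ndim(spacing) > 0 and np.size(spacing) == 2
    n_space = 2 if two_d else 1
    if vals.ndim < n_space + 1:
        raise ValueError("values must end in grid axes plus a channel axis")
    grid_shape = vals.shape[-(n_space + 1) : -1]
    if min(grid_shape) < l:
        raise ValueError("grid too small for the stencil")
    mode = "wrap" if boundary == "periodic" else "nearest"
    n_ch = vals.shape[-1]
    feats = []
    spacings = np.atleast_1d(np.asarray(spacing, float))
    for ch in range(n_ch):
        v = vals[..., ch]
        feats.append(v)
        for axis in range(n_space):
            ax = v.ndim - n_space + axis
            for order in range(1, n_derivs + 1):
                st = fd_coefficients(order, l, float(spacings[axis]))
                feats.append(correlate1d(v, st.coefficients, axis=ax, mode=mode))
    return np.stack(feats, axis=-1)


def interior_slice(l: int, n_space: int = 1) -> tuple:
    """Slices dropping (l-1)/2 stencil-contaminated points per side.

    The trailing ``slice(None)`` keeps the channel/feature axis intact, so
    the tuple applies to any (..., *grid_shape, channels)-shaped array.
    """
    hw = (l - 1) // 2
    return tuple([Ellipsis] + [slice(hw, -hw)] * n_space + [slice(None)])


# ---------------------------------------------------------------------------
# Model specification and MLP
# ---------------------------------------------------------------------------


@dataclass
class PDEModelSpec:
    """Architecture of the learned right-hand side f."""

    n_derivs: int
    channels: int = 2
    hidden_layers: int = 4
    width: int = 96
    activation: str = "swish"  # or "tanh"
    param_input: bool = False
    stencil_length: int = 5
    boundary: str = "periodic"  # "periodic" | "interior_only"
    n_space: int = 1
    spacing: Optional[tuple] = None

    @property
    def input_dim(self) -> int:
        d = self.channels * (self.n_space * self.n_derivs + 1)
        return d + 1 if self.param_input else d

    @property
    def output_dim(self) -> int:
        return self.channels


def _swish(z):
    return z / (1.0 + np.exp(-z))


def _swish_grad(z):
    s = 1.0 / (1.0 + np.exp(-z))
    return s + z * s * (1.0 - s)


def _tanh_grad(z):
    return 1.0 - np.tanh(z) ** 2


def _activation(name: str) -> tuple[Callable, Callable]:
    """(value, derivative-from-preactivation) pair."""
    if name == "swish":
        return _swish, _swish_grad
    if name == "tanh":
        return np.tanh, _tanh_grad
    raise ValueError(f"unknown activation {name!r}")


class MLP:
    """Plain fully connected network with explicit backprop on numpy arrays.

    Weight matrices W have shape (fan_in, fan_out); initialization is uniform
    in +-1/sqrt(fan_in) for weights and biases, fixed by the seed.
    """

    def __init__(self, sizes: list[int], activation: str = "swish", seed: int = 0):
        rng = np.random.default_rng(seed)
        self.sizes = list(sizes)
        self.activation = activation
        self.act, self.dact = _activation(activation)
        self.weights: list[NDArray] = []
        self.biases: list[NDArray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = 1.0 / np.sqrt(fan_in)
            self.weights.append(rng.uniform(-bound, bound, (fan_in, fan_out)))
            self.biases.append(rng.uniform(-bound, bound, fan_out))

    def forward(self, X: NDArray) -> NDArray:
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            a = self.act(a @ W + b)
        return a @ self.weights[-1] + self.biases[-1]

    def _forward_cached(self, X: NDArray):
        zs, acts = [], [X]
        a = X
        for W, b in zip(self.weights[:-1], self.biases[:-1]):
            z = a @ W + b
            zs.append(z)
            a = self.act(z)
            acts.append(a)
        out = a @ self.weights[-1] + self.biases[-1]
        return out, zs, acts

    def loss_and_grads(self, X: NDArray, Y: NDArray):
        """Mean-squared-error loss and its gradients w.r.t. all parameters."""
        out, zs, acts = self._forward_cached(X)
        m = X.shape[0]
        diff = out - Y
        loss = float(np.mean(diff**2))
        delta = (2.0 / (m * Y.shape[1])) * diff
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        gW[-1] = acts[-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        for layer in range(len(self.weights) - 2, -1, -1):
            delta = (delta @ self.weights[layer + 1].T) * self.dact(zs[layer])
            gW[layer] = acts[layer].T @ delta
            gb[layer] = delta.sum(axis=0)
        return loss, gW, gb

    @property
    def parameters(self) -> list[NDArray]:
        return self.weights + self.biases

    def state_dict(self) -> dict:
        d = {f"W{i}": W for i, W in enumerate(self.weights)}
        d.update({f"b{i}": b for i, b in enumerate(self.biases)})
        d["sizes"] = np.array(self.sizes)
        d["activation"] = np.array(self.activation)
        return d

    @classmethod
    def from_state_dict(cls, d: dict) -> "MLP":
        sizes = [int(s) for s in np.asarray(d["sizes"])]
        model = cls(sizes, activation=str(np.asarray(d["activation"])), seed=0)
        model.weights = [np.asarray(d[f"W{i}"]) for i in range(len(sizes) - 1)]
        model.biases = [np.asarray(d[f"b{i}"]) for i in range(len(sizes) - 1)]
        return model


@dataclass
class TrainConfig:
    """Adam + reduce-on-plateau hyperparameters."""

    lr: float = 2e-3
    batch: int = 128
    epochs: int = 400
    plateau_factor: float = 2.0
    patience: int = 10
    rel_tol: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.lr, self.batch, self.epochs, self.plateau_factor, self.patience) <= 0:
            raise ValueError("training hyperparameters must be positive")


@dataclass
class PDEModel:
    """A trained right-hand side: architecture spec plus network weights."""

    spec: PDEModelSpec
    net: MLP
    history: dict = field(default_factory=dict)

    def rhs_features(self, X: NDArray) -> NDArray:
        return self.net.forward(X)


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


def assemble_features(
    fields: NDArray[np.float64],
    targets: NDArray[np.float64],
    spec: PDEModelSpec,
    gamma: Optional[float] = None,
) -> tuple[NDArray, NDArray]:
    """Flatten gridded snapshots into supervised (features, d/dt) rows.

    ``fields`` is (timesteps, *grid, channels); ``targets`` matches with one
    fewer timestep (the final snapshot has no forward difference and is
    dropped from the inputs). In ``interior_only`` mode the contaminated
    boundary band is excluded from both.
    """
    if fields.shape[0] != targets.shape[0] + 1:
        raise ValueError("targets must have exactly one fewer timestep than fields")
    if spec.spacing is None:
        raise ValueError("spec.spacing must be set before assembling features")
    spacing = spec.spacing if spec.n_space == 2 else spec.spacing[0]
    feats = spatial_derivative_stack(
        fields[:-1], spec.n_derivs, spec.stencil_length, spacing, boundary=spec.boundary
    )
    tg = targets
    if spec.boundary == "interior_only":
        sl = interior_slice(spec.stencil_length, spec.n_space)
        feats = feats[sl]
        tg = tg[sl]
    X = feats.reshape(-1, feats.shape[-1])
    Y = tg.reshape(-1, tg.shape[-1])
    if spec.param_input:
        if gamma is None:
            raise ValueError("spec expects a parameter input but gamma is None")
        X = np.concatenate([X, np.full((X.shape[0], 1), float(gamma))], axis=1)
    elif gamma is not None:
        raise ValueError("gamma given but spec.param_input is False")
    if X.shape[1] != spec.input_dim:
        raise ValueError("assembled feature dimension does not match the spec")
    return X, Y


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


class _Adam:
    def __init__(self, params: list[NDArray], lr: float, betas=(0.9, 0.999), eps=1e-8):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[NDArray], grads: list[NDArray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g**2
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train_pde_model(
    spec: PDEModelSpec,
    X: NDArray,
    Y: NDArray,
    X_val: NDArray,
    Y_val: NDArray,
    cfg: TrainConfig,
    verbose: bool = False,
) -> PDEModel:
    """Train the right-hand-side network on supervised derivative pairs.

    Minimizes the MSE with Adam; the learning rate is divided by
    ``plateau_factor`` whenever the validation loss fails to improve by a
    relative ``rel_tol`` for ``patience`` consecutive epochs. Deterministic
    for fixed (seed, data, config).
    """
    if X.size == 0:
        raise ValueError("empty training set")
    sizes = [spec.input_dim] + [spec.width] * spec.hidden_layers + [spec.output_dim]
    net = MLP(sizes, activation=spec.activation, seed=cfg.seed)
    opt = _Adam(net.parameters, cfg.lr)
    rng = np.random.default_rng(cfg.seed + 1)
    n = X.shape[0]
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    stall = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        running, nb = 0.0, 0
        for start in range(0, n, cfg.batch):
            idx = order[start : start + cfg.batch]
            loss, gW, gb = net.loss_and_grads(X[idx], Y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}, batch {nb}"
                )
            opt.step(net.parameters, gW + gb)
            running += loss
            nb += 1
        val_pred = net.forward(X_val)
        val_loss = float(np.mean((val_pred - Y_val) ** 2))
        history["train_loss"].append(running / max(nb, 1))
        history["val_loss"].append(val_loss)
        history["lr"].append(opt.lr)
        if val_loss < best_val * (1.0 - cfg.rel_tol):
            best_val = val_loss
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                opt.lr /= cfg.plateau_factor
                stall = 0
        if verbose and (epoch % 10 == 0 or epoch == cfg.epochs - 1):
            print(f"epoch {epoch:4d}  train {history['train_loss'][-1]:.3e}  "
                  f"val {val_loss:.3e}  lr {opt.lr:.2e}")
    return PDEModel(spec=spec, net=net, history=history)


def predict_rhs(
    model: PDEModel,
    snapshot: NDArray[np.float64],
    gamma: Optional[float] = None,
) -> NDArray[np.float64]:
    """Apply the learned f to one gridded snapshot (*grid_shape, channels).

    Returns the predicted time derivative on the same grid; in
    ``interior_only`` mode, points whose stencil touches the boundary are
    returned as zero (the rollout overwrites them from the corridor).
    """
    spec = model.spec
    spacing = spec.spacing if spec.n_space == 2 else spec.spacing[0]
    snap = snapshot[None, ...]
    feats = spatial_derivative_stack(
        snap, spec.n_derivs, spec.stencil_length, spacing, boundary=spec.boundary
    )[0]
    out = np.zeros(snapshot.shape[:-1] + (spec.output_dim,))
    if spec.boundary == "interior_only":
        sl = tuple(interior_slice(spec.stencil_length, spec.n_space)[1:])
        feats_i = feats[sl]
        X = feats_i.reshape(-1, feats_i.shape[-1])
        if spec.param_input:
            X = np.concatenate([X, np.full((X.shape[0], 1), float(gamma))], axis=1)
        out[sl] = model.net.forward(X).reshape(feats_i.shape[:-1] + (spec.output_dim,))
    else:
        X = feats.reshape(-1, feats.shape[-1])
        if spec.param_input:
            X = np.concatenate([X, np.full((X.shape[0], 1), float(gamma))], axis=1)
        out = model.net.forward(X).reshape(snapshot.shape[:-1] + (spec.output_dim,))
    return out
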