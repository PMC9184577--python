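"""Finite-difference features and the right-hand-side network."""

import numpy as np
import pytest
import sympy

from empde.pde_learning import (
    MLP,
    PDEModel,
    PDEModelSpec,
    TrainConfig,
    assemble_features,
    fd_coefficients,
    predict_rhs,
    spatial_derivative_stack,
    train_pde_model,
)


def sympy_stencil(n, l):
    """Independent oracle: solve the Taylor-moment system exactly in rationals."""
    offsets = [sympy.Integer(j - l // 2) for j in range(l)]
    c = sympy.symbols(f"c0:{l}")
    eqs = []
    for m in range(l):
        s = sum(ci * oi**m / sympy.factorial(m) for ci, oi in zip(c, offsets))
        eqs.append(sympy.Eq(s, 1 if m == n else 0))
    sol = sympy.solve(eqs, c)
    return [sympy.nsimplify(sol[ci]) for ci in c]


class TestStencils:
    def test_classic_laplacian(self):
        st = fd_coefficients(2, 3)
        assert np.allclose(st.coefficients, [1.0, -2.0, 1.0])
        assert st.accuracy_order == 2

    def test_first_derivative_length_five(self):
        st = fd_coefficients(1, 5)
        assert np.allclose(st.coefficients,
                           [1 / 12, -2 / 3, 0.0, 2 / 3, -1 / 12], atol=1e-12)
        assert st.accuracy_order == 4

    @pytest.mark.parametrize("n,l", [(n, l) for l in range(3, 10, 2)
                                     for n in range(1, l)])
    def test_matches_symbolic_taylor_solver(self, n, l):
        """All (n, l) with n < l <= 9 agree with the exact rational solution."""
        st = fd_coefficients(n, l)
        exact = np.array([float(c) for c in sympy_stencil(n, l)])
        assert np.allclose(st.coefficients, exact, atol=1e-8)

    def test_annihilates_constants(self):
        for n in (1, 2, 3):
            st = fd_coefficients(n, 7)
            assert abs(st.coefficients.sum()) < 1e-10

    def test_spacing_scaling(self):
        a = fd_coefficients(2, 5, h=1.0).coefficients
        b = fd_coefficients(2, 5, h=0.5).coefficients
        assert np.allclose(b, a / 0.25)

    def test_invalid_orders_rejected(self):
        with pytest.raises(ValueError):
            fd_coefficients(5, 5)
        with pytest.raises(ValueError):
            fd_coefficients(1, 4)


class TestDerivativeStack:
    def test_sin_second_derivative_periodic(self):
        n = 128
        x = np.linspace(0, 2 * np.pi, n, endpoint=False)
        vals = np.sin(x)[None, :, None]
        feats = spatial_derivative_stack(vals, 2, 5, x[1] - x[0], "periodic")
        # features: [u, u_x, u_xx]
        assert np.max(np.abs(feats[0, :, 1] - np.cos(x))) < 1e-5
        assert np.max(np.abs(feats[0, :, 2] + np.sin(x))) < 1e-4

    def test_input_dimensions_match_configs(self):
        """Complex field, two spatial derivatives -> 6 network inputs;
        three derivatives -> 8; adding the parameter input -> 9."""
        assert PDEModelSpec(n_derivs=2, channels=2).input_dim == 6
        assert PDEModelSpec(n_derivs=3, channels=2).input_dim == 8
        assert PDEModelSpec(n_derivs=3, channels=2, param_input=True).input_dim == 9
        # 2D Hodgkin-Huxley configuration: (V,h) x (1 + 3 per axis)
        assert PDEModelSpec(n_derivs=3, channels=2, n_space=2).input_dim == 14

    def test_2d_per_axis_no_mixed(self):
        n = 32
        x = np.linspace(0, 2 * np.pi, n, endpoint=False)
        X, Y = np.meshgrid(x, x, indexing="ij")
        vals = (np.sin(X) * np.cos(Y))[None, :, :, None]
        h = x[1] - x[0]
        feats = spatial_derivative_stack(vals, 1, 5, (h, h), "periodic")
        # [u, u_x, u_y]
        assert feats.shape[-1] == 3
        assert np.max(np.abs(feats[0, :, :, 1] - np.cos(X) * np.cos(Y))) < 1e-4
        assert np.max(np.abs(feats[0, :, :, 2] + np.sin(X) * np.sin(Y))) < 1e-4

    def test_grid_too_small_rejected(self):
        with pytest.raises(ValueError):
            spatial_derivative_stack(np.zeros((1, 4, 1)), 1, 5, 0.1)


class TestAssemble:
    def _spec(self, **kw):
        defaults = dict(n_derivs=2, channels=2, stencil_length=5,
                        boundary="periodic", n_space=1, spacing=(0.1,))
        defaults.update(kw)
        return PDEModelSpec(**defaults)

    def test_sample_count_formula(self, rng):
        fields = rng.standard_normal((11, 32, 2))
        targets = np.diff(fields, axis=0) / 0.1
        X, Y = assemble_features(fields, targets, self._spec())
        assert X.shape == (10 * 32, 6)
        assert Y.shape == (10 * 32, 2)

    def test_interior_mode_drops_boundary_band(self, rng):
        fields = rng.standard_normal((5, 40, 2))
        targets = np.diff(fields, axis=0) / 0.1
        spec = self._spec(boundary="interior_only", stencil_length=9)
        X, _ = assemble_features(fields, targets, spec)
        assert X.shape[0] == 4 * (40 - 8)

    def test_gamma_column(self, rng):
        fields = rng.standard_normal((3, 16, 2))
        targets = np.diff(fields, axis=0) / 0.1
        spec = self._spec(n_derivs=3, param_input=True)
        X, _ = assemble_features(fields, targets, spec, gamma=1.75)
        assert X.shape[1] == 9
        assert np.all(X[:, -1] == 1.75)
        with pytest.raises(ValueError):
            assemble_features(fields, targets, spec)  # missing gamma
        with pytest.raises(ValueError):
            assemble_features(fields, targets, self._spec(), gamma=1.75)

    def test_shape_mismatch_rejected(self, rng):
        fields = rng.standard_normal((5, 16, 2))
        with pytest.raises(ValueError):
            assemble_features(fields, fields, self._spec())


class TestMLP:
    def test_zero_output_layer_gives_zero_field(self, rng):
        spec = PDEModelSpec(n_derivs=2, channels=2, stencil_length=5,
                            boundary="periodic", n_space=1, spacing=(0.1,))
        net = MLP([6, 16, 16, 2], "swish", seed=0)
        net.weights[-1][:] = 0.0
        net.biases[-1][:] = 0.0
        model = PDEModel(spec, net)
        out = predict_rhs(model, rng.standard_normal((32, 2)))
        assert np.all(out == 0.0)

    def test_gradients_match_finite_differences(self, rng):
        net = MLP([3, 8, 2], "tanh", seed=1)
        X = rng.standard_normal((20, 3))
        Y = rng.standard_normal((20, 2))
        loss, gW, gb = net.loss_and_grads(X, Y)
        h = 1e-6
        W = net.weights[0]
        for idx in [(0, 0), (2, 5)]:
            W[idx] += h
            lp = float(np.mean((net.forward(X) - Y) ** 2))
            W[idx] -= 2 * h
            lm = float(np.mean((net.forward(X) - Y) ** 2))
            W[idx] += h
            assert gW[0][idx] == pytest.approx((lp - lm) / (2 * h), rel=1e-4)

    def test_initialization_is_uniform_fan_in(self):
        net = MLP([100, 50, 2], "tanh", seed=0)
        bound = 1.0 / np.sqrt(100)
        assert np.abs(net.weights[0]).max() <= bound
        assert np.abs(net.weights[0]).max() > 0.9 * bound

    def test_state_dict_roundtrip(self, rng):
        net = MLP([4, 8, 3], "swish", seed=2)
        clone = MLP.from_state_dict(net.state_dict())
        X = rng.standard_normal((5, 4))
        assert np.array_equal(net.forward(X), clone.forward(X))


class TestTraining:
    def _toy_data(self, rng, n=2000):
        X = rng.standard_normal((n, 6))
        Y = np.stack([X[:, 0] - 0.5 * X[:, 2], X[:, 1] * 0.3 + X[:, 5]], axis=1)
        return X, Y

    def _spec(self):
        return PDEModelSpec(n_derivs=2, channels=2, hidden_layers=2, width=16,
                            activation="tanh", stencil_length=5,
                            boundary="periodic", n_space=1, spacing=(0.1,))

    def test_loss_decreases(self, rng):
        X, Y = self._toy_data(rng)
        cfg = TrainConfig(lr=1e-2, batch=64, epochs=20, patience=5, seed=0)
        spec = self._spec()
        spec.channels = 2
        model = train_pde_model(spec, X[:-200], Y[:-200], X[-200:], Y[-200:], cfg)
        hist = model.history
        assert hist["val_loss"][-1] < hist["val_loss"][0]
        assert hist["train_loss"][-1] < 1e-2

    def test_bit_reproducible(self, rng):
        X, Y = self._toy_data(rng, 500)
        cfg = TrainConfig(lr=1e-2, batch=64, epochs=5, patience=3, seed=7)
        m1 = train_pde_model(self._spec(), X[:-100], Y[:-100], X[-100:], Y[-100:], cfg)
        m2 = train_pde_model(self._spec(), X[:-100], Y[:-100], X[-100:], Y[-100:], cfg)
        for a, b in zip(m1.net.parameters, m2.net.parameters):
            assert np.array_equal(a, b)

    def test_plateau_reduces_learning_rate(self, rng):
        X, Y = self._toy_data(rng, 300)
        # absurdly high patience threshold: rate must drop at least once
        cfg = TrainConfig(lr=1e-3, batch=64, epochs=30, patience=2, seed=0,
                          rel_tol=0.5)
        model = train_pde_model(self._spec(), X[:-50], Y[:-50], X[-50:], Y[-50:], cfg)
        assert model.history["lr"][-1] < cfg.lr

    def test_nonfinite_loss_aborts(self, rng):
        X, Y = self._toy_data(rng, 200)
        X[0, 0] = np.inf
        cfg = TrainConfig(lr=1e-2, batch=64, epochs=2, patience=2, seed=0)
        with pytest.raises(FloatingPointError):
            train_pde_model(self._spec(), X, Y, X[:10], Y[:10], cfg)

    def test_empty_dataset_rejected(self):
        cfg = TrainConfig()
        with pytest.raises(ValueError):
            train_pde_model(self._spec(), np.empty((0, 6)), np.empty((0, 2)),
                            np.empty((0, 6)), np.empty((0, 2)), cfg)
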