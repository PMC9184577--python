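"""Diffusion maps: kernel, spectrum, mode selection, circular coordinates."""

import numpy as np
import pytest

from empde import (
    circular_coordinate,
    compute_kernel_matrix,
    diffusion_eigendecomposition,
    scale_modes,
    select_independent_modes,
)
from empde.emergent_coords import embed_features


def circle_features(n=200, radius=1.0, seed=0, jitter=0.0):
    rng = np.random.default_rng(seed)
    theta = 2 * np.pi * np.arange(n) / n
    pts = radius * np.stack([np.cos(theta), np.sin(theta)], axis=1)
    if jitter:
        pts += jitter * rng.standard_normal(pts.shape)
    return pts, theta


class TestKernel:
    def test_identical_rows_give_unit_entry(self):
        X = np.ones((4, 3))
        K = compute_kernel_matrix(X, 1.0)
        assert np.allclose(K, 1.0)

    def test_large_eps_limit(self, rng):
        X = rng.standard_normal((10, 4))
        K = compute_kernel_matrix(X, 1e12)
        assert np.all(K > 0.999)

    def test_symmetric_unit_diagonal(self, rng):
        X = rng.standard_normal((20, 6))
        K = compute_kernel_matrix(X, 2.0)
        assert np.array_equal(K, K.T)
        assert np.allclose(np.diag(K), 1.0)

    def test_rejects_nonfinite(self):
        X = np.ones((3, 2))
        X[1, 0] = np.inf
        with pytest.raises(ValueError):
            compute_kernel_matrix(X, 1.0)


class TestEigendecomposition:
    def test_trivial_mode_is_constant_with_unit_eigenvalue(self, rng):
        X = rng.standard_normal((30, 5))
        K = compute_kernel_matrix(X, 5.0)
        dr = diffusion_eigendecomposition(K, n_modes=6)
        assert dr.eigenvalues[0] == pytest.approx(1.0, abs=1e-10)
        v0 = dr.eigenvectors[:, 0]
        assert np.ptp(v0) < 1e-9 * np.abs(v0).max()

    def test_row_normalization_and_real_spectrum(self, rng):
        X = rng.standard_normal((25, 4))
        K = compute_kernel_matrix(X, 3.0)
        d = K.sum(axis=1)
        A = K / d[:, None]
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-12)
        dr = diffusion_eigendecomposition(K, n_modes=8)
        # right eigenvectors of the row-normalized matrix
        for k in range(4):
            lhs = A @ dr.eigenvectors[:, k]
            assert np.allclose(lhs, dr.eigenvalues[k] * dr.eigenvectors[:, k],
                               atol=1e-9)

    def test_circle_modes_have_constant_radius(self):
        """Points uniform on a circle: the two leading nontrivial modes are a
        sin/cos pair, so phi1^2 + phi2^2 is nearly constant."""
        pts, _ = circle_features(200)
        K = compute_kernel_matrix(pts, 0.05)
        dr = diffusion_eigendecomposition(K, n_modes=5)
        r2 = dr.eigenvectors[:, 1] ** 2 + dr.eigenvectors[:, 2] ** 2
        assert r2.std() / r2.mean() < 0.05

    def test_segment_mode_is_monotone(self):
        """Points on a 1D segment: the leading nontrivial eigenvector is the
        discrete slowest Laplacian mode, strictly monotone along the line."""
        x = np.linspace(0, 1, 60)[:, None]
        K = compute_kernel_matrix(x, 0.005)
        dr = diffusion_eigendecomposition(K, n_modes=4)
        phi1 = dr.eigenvectors[:, 1]
        diffs = np.diff(phi1)
        assert np.all(diffs > 0) or np.all(diffs < 0)

    def test_zero_row_sum_rejected(self):
        K = np.zeros((3, 3))
        with pytest.raises(ValueError):
            diffusion_eigendecomposition(K)

    def test_permutation_invariance(self, rng):
        """Scrambling the input rows permutes the per-agent coordinates and
        changes nothing else (up to sign)."""
        pts, _ = circle_features(80, jitter=0.01, seed=3)
        perm = rng.permutation(80)
        dr1 = diffusion_eigendecomposition(compute_kernel_matrix(pts, 0.1), 4)
        dr2 = diffusion_eigendecomposition(compute_kernel_matrix(pts[perm], 0.1), 4)
        for k in range(1, 3):
            a = dr1.eigenvectors[perm, k]
            b = dr2.eigenvectors[:, k]
            assert min(np.max(np.abs(a - b)), np.max(np.abs(a + b))) < 1e-8


class TestModeSelection:
    def test_manual_selection(self):
        pts, _ = circle_features(100)
        K = compute_kernel_matrix(pts, 0.1)
        dr = diffusion_eigendecomposition(K, n_modes=6)
        assert select_independent_modes(dr, "manual", {"indices": [1, 2]}) == [1, 2]

    def test_llr_keeps_circle_pair_rejects_harmonics(self):
        pts, _ = circle_features(150)
        K = compute_kernel_matrix(pts, 0.05)
        dr = diffusion_eigendecomposition(K, n_modes=12)
        sel = select_independent_modes(dr, "local_linear_regression",
                                       {"threshold": 0.5})
        assert sel[:2] == [1, 2]
        # higher circle harmonics (cos 2t, sin 2t, ...) are functions of the
        # first pair and must be rejected
        assert all(k not in sel for k in (3, 4, 5, 6))

    def test_empty_selection_raises(self):
        pts, _ = circle_features(60)
        K = compute_kernel_matrix(pts, 0.1)
        dr = diffusion_eigendecomposition(K, n_modes=6)
        with pytest.raises((ValueError, KeyError)):
            select_independent_modes(dr, "manual", {"indices": []})


class TestCircularCoordinate:
    def test_cardinal_angles(self):
        coord = circular_coordinate(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert coord.values[0] == pytest.approx(0.0)
        assert coord.values[1] == pytest.approx(np.pi / 2)

    def test_range_half_open(self):
        phi = np.array([-1.0, 1.0, 0.0])
        psi = np.array([0.0, 0.0, -1.0])
        coord = circular_coordinate(phi, psi)
        assert np.all(coord.values >= -np.pi) and np.all(coord.values < np.pi)

    def test_reflection_flips_orientation_preserves_neighbors(self):
        _, theta = circle_features(50)
        phi1, phi2 = np.cos(theta), np.sin(theta)
        a = circular_coordinate(phi1, phi2).values
        b = circular_coordinate(phi1, phi2, orientation_sign=-1).values
        # the reflected angle is the negated angle (modulo the 2*pi wrap)
        assert np.allclose(np.exp(1j * b), np.exp(-1j * a), atol=1e-12)

    def test_origin_rejected(self):
        with pytest.raises(ValueError):
            circular_coordinate(np.array([0.0, 1.0]), np.array([0.0, 0.0]))


class TestScaleModes:
    def _embedded(self):
        pts, _ = circle_features(100)
        dr = diffusion_eigendecomposition(compute_kernel_matrix(pts, 0.05), 6)
        select_independent_modes(dr, "manual", {"indices": [1, 2]})
        return dr

    def test_range_is_exactly_pm1(self):
        dr = scale_modes(self._embedded())
        assert dr.scaled_modes.min(axis=0) == pytest.approx([-1.0, -1.0])
        assert dr.scaled_modes.max(axis=0) == pytest.approx([1.0, 1.0])

    def test_affine_mapping_recorded_and_idempotent(self):
        dr = scale_modes(self._embedded())
        (lo, hi) = dr.scaling[0]
        rebuilt = 2 * (dr.eigenvectors[:, 1] - lo) / (hi - lo) - 1
        assert np.allclose(rebuilt, dr.scaled_modes[:, 0], atol=1e-12)
        once = dr.scaled_modes.copy()
        dr.eigenvectors[:, 1] = dr.scaled_modes[:, 0]
        dr2 = scale_modes(dr)
        assert np.allclose(dr2.scaled_modes[:, 0], once[:, 0], atol=1e-12)

    def test_constant_mode_rejected(self):
        dr = self._embedded()
        dr.eigenvectors[:, 1] = 0.5
        dr.selected = [1]
        with pytest.raises(ValueError):
            scale_modes(dr)


def test_hh_embedding_resolves_applied_current():
    """The neuron network's two emergent coordinates parametrize its kinetic
    heterogeneity: a quadratic fit of the applied current I_app over
    (phi_1, phi_2) attains R^2 > 0.95."""
    from empde import HHNetworkParams, rescale_hh, simulate_hh_network

    params = HHNetworkParams.random(256, seed=0)
    traj = simulate_hh_network(params, t_span=(0.0, 130.0), t_min=120.0,
                               dt_sample=0.01)
    feats = rescale_hh(traj).states.reshape(256, -1).astype(float)
    dr = embed_features(feats, eps="median", n_modes=12,
                        selection_params={"threshold": 0.5, "max_modes": 2})
    assert len(dr.selected) == 2
    p1, p2 = dr.scaled_modes[:, 0], dr.scaled_modes[:, 1]
    X = np.stack([np.ones_like(p1), p1, p2, p1 * p2, p1**2, p2**2], axis=1)
    beta, *_ = np.linalg.lstsq(X, params.I_app, rcond=None)
    r2 = 1.0 - (params.I_app - X @ beta).var() / params.I_app.var()
    assert r2 > 0.95


def test_embed_features_end_to_end_circle():
    pts, theta = circle_features(120, jitter=0.005, seed=1)
    dr = embed_features(pts, eps="nn_median", n_modes=8,
                        selection_params={"threshold": 0.5, "max_modes": 2})
    assert len(dr.selected) == 2
    ang = circular_coordinate(dr.scaled_modes[:, 0], dr.scaled_modes[:, 1]).values
    from empde.analysis import circular_rank_correlation

    assert circular_rank_correlation(ang, theta) > 0.99
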