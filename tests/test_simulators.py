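"""Ground-truth simulators: CGLE, Stuart-Landau, Floquet, Chung-Lu, HH."""

import numpy as np
import pytest

from empde import (
    CGLEParams,
    DivergedSimulationError,
    HHNetworkParams,
    NoCycleError,
    SLEnsembleParams,
    TrajectoryEnsemble,
    build_chung_lu_adjacency,
    compute_monodromy,
    find_limit_cycle,
    rescale_hh,
    simulate_cgle,
    simulate_hh_network,
    simulate_sl_ensemble,
    sl_jacobian,
    unscale_hh,
)
from empde.simulators import (
    chung_lu_edge_probabilities,
    hh_hinf,
    hh_m,
    hh_s,
    hh_tau,
    sl_jacobian_apply,
    _sl_real_rhs_factory,
)


class TestCGLE:
    def test_uniform_field_follows_radial_ode(self):
        """A spatially uniform state has vanishing diffusion: |W| obeys
        d|W|/dt = |W| - |W|^3 and relaxes to 1."""
        p = CGLEParams(c1=0.0, c2=-3.0, L=80.0, n_mesh=64, dt_sample=0.1)
        traj = simulate_cgle(p, ic=np.full(64, 0.3 + 0j), t_burn=0.0,
                             t_sample=10.0, dt_internal=0.002)
        W = traj.as_complex()
        assert np.max(np.abs(W - W.mean(axis=0))) < 1e-9  # stays uniform
        # closed-form radial solution r(t) for r' = r - r^3
        r0 = 0.3
        t = traj.times
        r_exact = 1.0 / np.sqrt(1.0 + (1.0 / r0**2 - 1.0) * np.exp(-2.0 * t))
        assert np.allclose(np.abs(W[0]), r_exact, atol=1e-4)

    def test_chaotic_attractor_is_bounded_and_nonrepeating(self):
        p = CGLEParams(c1=0.0, c2=-3.0, L=80.0, n_mesh=128, dt_sample=0.05)
        traj = simulate_cgle(p, seed=0, t_burn=300.0, t_sample=20.0)
        W = traj.as_complex()
        assert np.abs(W).max() < 2.0
        # spatiotemporal intermittency: distinct snapshots stay well separated
        d = np.linalg.norm(W[:, -1] - W[:, 0])
        assert d > 0.1 * np.linalg.norm(W[:, 0])

    def test_etd_second_order_convergence(self):
        """The exponential time stepping converges at second order: halving
        the internal step cuts the error against a fine-step reference by
        about four."""
        p = CGLEParams(c1=0.0, c2=-3.0, L=80.0, n_mesh=64, dt_sample=0.02)
        ic = 0.1 * np.exp(2j * np.pi * np.arange(64) / 64) + 0.5
        ref = simulate_cgle(p, ic=ic, t_burn=0.0, t_sample=1.0, dt_internal=0.000625)
        errs = []
        for h in (0.01, 0.005, 0.0025):
            run = simulate_cgle(p, ic=ic, t_burn=0.0, t_sample=1.0, dt_internal=h)
            errs.append(np.max(np.abs(run.states - ref.states)))
        assert 2.5 < errs[0] / errs[1] < 6.0
        assert 2.5 < errs[1] / errs[2] < 6.0

    def test_noflux_long_run_bounded_and_structured(self):
        """Under zero-flux boundaries the cosine IC evolves into a bounded,
        spatially structured oscillatory state (no decay, no blow-up)."""
        p = CGLEParams(c1=1.0, c2=2.0, L=200.0, n_mesh=96, boundary="no_flux",
                       dt_sample=0.05)
        x = p.x
        ic = ((1.0 + np.cos(np.pi * x / p.L)) / 2.0).astype(complex)
        traj = simulate_cgle(p, ic=ic, t_burn=500.0, t_sample=40.0)
        amp = np.abs(traj.as_complex())
        assert 0.05 < amp.mean() < 1.5  # alive, not diverged
        profile = amp.mean(axis=1)  # time-averaged spatial structure
        assert profile.std() > 0.02 * profile.mean()
        # the field oscillates in time
        assert amp.std(axis=1).max() > 0.01

    def test_noflux_matches_independent_integrator_short_time(self):
        """Cross-check of the stiff-multistep no-flux integration against an
        independent scheme (BDF) over a short window."""
        from scipy.integrate import solve_ivp

        from empde.simulators import _cgle_noflux_rhs_factory

        p = CGLEParams(c1=1.0, c2=2.0, L=200.0, n_mesh=64, boundary="no_flux",
                       dt_sample=0.1)
        x = p.x
        ic = ((1.0 + np.cos(np.pi * x / p.L)) / 2.0).astype(complex)
        traj = simulate_cgle(p, ic=ic, t_burn=0.0, t_sample=5.0)
        rhs = _cgle_noflux_rhs_factory(p)
        y0 = np.concatenate([ic.real, ic.imag])
        ref = solve_ivp(rhs, (0.0, 5.0), y0, method="BDF", rtol=1e-9,
                        atol=1e-11, t_eval=traj.times)
        W_ref = (ref.y[:64] + 1j * ref.y[64:])
        assert np.max(np.abs(traj.as_complex() - W_ref)) < 1e-4

    def test_ic_length_mismatch_raises(self):
        p = CGLEParams(c1=0.0, c2=-3.0, L=80.0, n_mesh=64)
        with pytest.raises(ValueError):
            simulate_cgle(p, ic=np.zeros(32, complex))

    def test_divergence_detected(self):
        # destabilize with a huge negative nonlinearity sign flip via c2 != real use:
        p = CGLEParams(c1=0.0, c2=-3.0, L=80.0, n_mesh=64, dt_sample=0.5)
        with pytest.raises(DivergedSimulationError):
            simulate_cgle(p, ic=np.full(64, 1e5 + 0j), t_burn=0.0, t_sample=5.0,
                          dt_internal=0.5)


class TestSLEnsemble:
    def test_uncoupled_amplitudes_relax_to_one(self):
        p = SLEnsembleParams(K=0.0, gamma=1.7, omega0=0.2, n_osc=16)
        traj = simulate_sl_ensemble(p, seed=0, t_span=(0.0, 40.0), dt_sample=0.1)
        amps = np.abs(traj.as_complex())
        assert np.allclose(amps[:, -1], 1.0, atol=1e-3)

    def test_uncoupled_matches_analytic_single_oscillator(self):
        """K=0 decouples the ensemble; each W_k follows the closed-form
        amplitude r(t) and phase w_k t of the Stuart-Landau normal form."""
        p = SLEnsembleParams(K=0.0, gamma=1.0, omega0=0.0, n_osc=8)
        ic = np.full(8, 0.5 + 0.0j)
        traj = simulate_sl_ensemble(p, ic=ic, t_span=(0.0, 30.0), dt_sample=0.05)
        W = traj.as_complex()
        t = traj.times
        r = 1.0 / np.sqrt(1.0 + (1.0 / 0.25 - 1.0) * np.exp(-2.0 * t))
        late = t > 20.0
        assert np.max(np.abs(np.abs(W[:, late]) - r[late])) < 1e-3

    def test_omegas_linspace_endpoints(self):
        p = SLEnsembleParams(K=1.2, gamma=1.7, omega0=0.2, n_osc=11)
        assert p.omegas[0] == pytest.approx(-1.5)
        assert p.omegas[-1] == pytest.approx(1.9)
        assert np.allclose(np.diff(p.omegas), p.omegas[1] - p.omegas[0])

    def test_oscillator_death_above_hopf(self):
        p = SLEnsembleParams(K=1.2, gamma=1.8, omega0=0.2, n_osc=64)
        traj = simulate_sl_ensemble(p, seed=0, t_span=(0.0, 300.0), dt_sample=1.0)
        final = np.abs(traj.as_complex()[:, -1])
        assert np.all(final < 1e-3)


class TestSLJacobian:
    def test_block_diagonal_when_uncoupled(self):
        p = SLEnsembleParams(K=0.0, gamma=1.0, omega0=0.0, n_osc=4)
        state = np.array([0.3 + 0.1j, -0.2 + 0.4j, 0.0 + 0.0j, 1.0 + 0.0j])
        J = sl_jacobian(state, p)
        n = 4
        for i in range(n):
            for j in range(n):
                if i != j:
                    assert J[i, j] == 0 and J[i + n, j + n] == 0
                assert J[i, j + n] == 0 or i == j  # no cross-oscillator Re/Im mix

    def test_coupling_entries_are_k_over_n(self):
        p = SLEnsembleParams(K=1.2, gamma=1.0, omega0=0.0, n_osc=5)
        J = sl_jacobian(np.zeros(5, complex), p)
        assert J[0, 1] == pytest.approx(1.2 / 5)
        assert J[7, 8] == pytest.approx(1.2 / 5)
        assert J[0, 6] == 0.0  # no Re-Im coupling from the mean field

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_central_difference(self, seed):
        """J delta agrees with (F(x+h d)-F(x-h d))/2h to O(h^2)."""
        rng = np.random.default_rng(seed)
        p = SLEnsembleParams(K=1.2, gamma=1.7, omega0=0.2, n_osc=12)
        rhs = _sl_real_rhs_factory(p)
        x = rng.standard_normal(24) * 0.6
        d = rng.standard_normal(24)
        d /= np.linalg.norm(d)
        h = 1e-6
        fd = (rhs(0.0, x + h * d) - rhs(0.0, x - h * d)) / (2 * h)
        J = sl_jacobian(x[:12] + 1j * x[12:], p)
        assert np.linalg.norm(J @ d - fd) < 1e-7 * max(1.0, np.linalg.norm(fd))

    def test_structured_apply_equals_dense(self, rng):
        p = SLEnsembleParams(K=1.2, gamma=1.7, omega0=0.2, n_osc=10)
        W = rng.standard_normal(10) + 1j * rng.standard_normal(10)
        V = rng.standard_normal((20, 7))
        dense = sl_jacobian(W, p) @ V
        assert np.allclose(sl_jacobian_apply(W, p, V), dense, atol=1e-12)


class TestLimitCycleDetection:
    def test_single_oscillator_period_is_2pi(self):
        p = SLEnsembleParams(K=0.0, gamma=0.0, omega0=1.0, n_osc=1)
        traj = simulate_sl_ensemble(p, ic=np.array([1.0 + 0j]),
                                    t_span=(0.0, 20.0), dt_sample=0.01)
        lc = find_limit_cycle(traj)
        assert lc.period == pytest.approx(2 * np.pi, abs=1e-6)

    def test_synthetic_sine_period(self):
        t = np.arange(0.0, 60.0, 0.05)
        s = np.sin(0.4 * t)
        traj = TrajectoryEnsemble(t, s[None, :, None].repeat(2, axis=2))
        lc = find_limit_cycle(traj, tol_per=1e-3)
        assert abs(lc.period - 2 * np.pi / 0.4) < 0.05

    def test_fixed_point_raises_no_cycle(self):
        p = SLEnsembleParams(K=1.2, gamma=1.8, omega0=0.2, n_osc=32)
        traj = simulate_sl_ensemble(p, seed=0, t_span=(0.0, 400.0), dt_sample=0.05)
        idx = traj.times >= 350.0
        tail = TrajectoryEnsemble(traj.times[idx], traj.states[:, idx, :])
        with pytest.raises(NoCycleError):
            find_limit_cycle(tail)


class TestMonodromy:
    @pytest.mark.parametrize("omega", [0.5, 1.0, 2.0])
    def test_single_oscillator_multipliers(self, omega):
        """Analytic oracle: the circular orbit W = e^{i w t} has multipliers
        {1, e^{-4 pi / w}} (radial Floquet exponent -2 over period 2 pi/w)."""
        p = SLEnsembleParams(K=0.0, gamma=0.0, omega0=omega, n_osc=1)
        T = 2 * np.pi / omega
        traj = simulate_sl_ensemble(p, ic=np.array([1.0 + 0j]),
                                    t_span=(0.0, 3 * T), dt_sample=T / 600)
        lc = find_limit_cycle(traj)
        fr = compute_monodromy(lc, p, n_steps=512)
        mags = np.sort(np.abs(fr.multipliers))[::-1]
        assert abs(mags[0] - 1.0) < 1e-4
        assert abs(mags[1] - np.exp(-4 * np.pi / omega)) < 1e-4

    def test_ensemble_neutral_multiplier_and_residual(self, sl_small_floquet):
        fr = sl_small_floquet
        assert abs(np.abs(fr.multipliers[0]) - 1.0) < 1e-3
        assert fr.residual < 1e-6 * np.abs(fr.monodromy).max()
        # eigen-consistency for the top three pairs
        for k in range(3):
            lam, v = fr.multipliers[k], fr.directions[:, k]
            assert np.linalg.norm(fr.monodromy @ v - lam * v) < 1e-6

    def test_matches_flow_map_oracle(self, sl_small_cycle, sl_small_params,
                                     sl_small_floquet):
        """Leading multipliers agree with a finite-difference flow map of the
        true ODE (independent oracle)."""
        from scipy.integrate import solve_ivp

        p = sl_small_params
        lc = sl_small_cycle
        rhs = _sl_real_rhs_factory(p)
        x0 = np.concatenate([lc.anchor[:, 0], lc.anchor[:, 1]])
        T = lc.period

        def flow(x):
            s = solve_ivp(rhs, (0, T), x, method="LSODA", rtol=1e-11,
                          atol=1e-13, t_eval=[T])
            return s.y[:, 0]

        xT = flow(x0)
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(2):
            d = rng.standard_normal(2 * p.n_osc)
            d /= np.linalg.norm(d)
            fd = (flow(x0 + h * d) - xT) / h
            Vd = sl_small_floquet.monodromy @ d
            assert np.linalg.norm(fd - Vd) < 5e-3 * max(np.linalg.norm(fd), 1e-3)


class TestChungLu:
    def test_structure(self):
        A = build_chung_lu_adjacency(64, 0.9, 0.25, seed=0)
        assert np.array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)
        assert set(np.unique(A)) <= {0, 1}

    def test_p_zero_gives_empty_graph(self):
        A = build_chung_lu_adjacency(32, 0.0, 0.25, seed=0)
        assert A.sum() == 0

    def test_degrees_match_expected(self):
        """Monte-Carlo oracle: empirical degrees converge to the column sums
        of the edge-probability matrix within a 3-sigma binomial bound."""
        n, reps = 128, 30
        P = chung_lu_edge_probabilities(n, 0.9, 0.25)
        expected = P.sum(axis=0)
        var = (P * (1 - P)).sum(axis=0) / reps
        degs = np.zeros(n)
        for s in range(reps):
            degs += build_chung_lu_adjacency(n, 0.9, 0.25, seed=1000 + s).sum(axis=0)
        degs /= reps
        z = np.abs(degs - expected) / np.sqrt(var)
        # per-node z-scores: essentially all within 3 sigma, none extreme
        assert np.mean(z < 3.0) > 0.97
        assert z.max() < 5.0

    def test_reproducible(self):
        a = build_chung_lu_adjacency(64, 0.9, 0.25, seed=7)
        b = build_chung_lu_adjacency(64, 0.9, 0.25, seed=7)
        assert np.array_equal(a, b)


class TestHodgkinHuxley:
    def test_gate_midpoints(self):
        assert hh_m(-37.0) == pytest.approx(0.5)
        assert hh_hinf(-44.0) == pytest.approx(0.5)
        assert hh_s(-40.0) == pytest.approx(0.5)
        assert hh_tau(-40.0, eps=0.1) == pytest.approx(10.0)

    def test_identical_neurons_stay_identical(self):
        """With no synaptic coupling and identical applied currents, the
        permutation symmetry forces all neurons to move in lockstep."""
        params = HHNetworkParams.random(16, seed=0, g_syn=0.0)
        params.I_app = np.full(16, 22.0)
        traj = simulate_hh_network(params, t_span=(0.0, 5.0), t_min=0.0,
                                   dt_sample=0.01)
        spread = np.ptp(traj.states, axis=0)
        assert spread.max() < 1e-6

    def test_collective_periodic_dynamics(self):
        """The coupled heterogeneous network settles into a collective
        time-periodic state with neurons dispersed at each instant."""
        params = HHNetworkParams.random(128, seed=3)
        traj = simulate_hh_network(params, t_span=(0.0, 60.0), t_min=40.0,
                                   dt_sample=0.01)
        V = traj.states[:, :, 0].astype(float)
        mean_v = V.mean(axis=0)
        assert mean_v.std() > 0.3  # collective oscillation
        assert np.median(V.std(axis=0)) > 0.5  # neurons spread out
        lc = find_limit_cycle(traj, tol_per=1e-2, amplitude_tol=1e-3)
        assert lc.period < 20.0

    def test_rescale_roundtrip_and_anchors(self):
        params = HHNetworkParams.random(8, seed=0)
        t = np.arange(3) * 0.1
        states = np.stack([
            np.array([[-37.0, -7.0, 23.0]] * 8),
            np.array([[0.42, 0.62, 0.22]] * 8),
        ], axis=-1)
        traj = TrajectoryEnsemble(t, states)
        rs = rescale_hh(traj)
        assert rs.states[0, 0, 0] == pytest.approx(0.0)  # V=-37 -> 0
        assert rs.states[0, 1, 0] == pytest.approx(1.0)  # V=-7 -> 1
        assert rs.states[0, 0, 1] == pytest.approx(0.0)  # h=0.42 -> 0
        back = unscale_hh(rs)
        assert np.allclose(back.states, traj.states, atol=1e-12)

    def test_iapp_range_enforced(self):
        params = HHNetworkParams.random(8, seed=0)
        params.I_app = np.full(8, 30.0)
        with pytest.raises(ValueError):
            params.validate()


class TestTrajectoryEnsemble:
    def test_rejects_nonmonotone_times(self):
        with pytest.raises(ValueError):
            TrajectoryEnsemble(np.array([0.0, 0.0, 1.0]), np.zeros((2, 3, 2)))

    def test_rejects_nan(self):
        states = np.zeros((2, 3, 2))
        states[0, 1, 0] = np.nan
        with pytest.raises(ValueError):
            TrajectoryEnsemble(np.arange(3.0), states)

    def test_complex_roundtrip(self, rng):
        W = rng.standard_normal((4, 5)) + 1j * rng.standard_normal((4, 5))
        traj = TrajectoryEnsemble.from_complex(np.arange(5.0), W)
        assert np.allclose(traj.as_complex(), W)
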