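"""Shared fixtures: small, settled reference systems reused across tests."""

import numpy as np
import pytest

from empde import (
    SLEnsembleParams,
    TrajectoryEnsemble,
    compute_monodromy,
    find_limit_cycle,
    simulate_sl_ensemble,
)


@pytest.fixture(scope="session")
def sl_small_params():
    """Synchronized Stuart-Landau ensemble at desk scale (N=48)."""
    return SLEnsembleParams(K=1.2, gamma=1.7, omega0=0.2, n_osc=48)


@pytest.fixture(scope="session")
def sl_small_cycle(sl_small_params):
    """Settled tail of the N=48 ensemble plus its detected limit cycle."""
    traj = simulate_sl_ensemble(sl_small_params, seed=1, t_span=(0.0, 400.0),
                                dt_sample=0.05)
    idx = traj.times >= 300.0
    tail = TrajectoryEnsemble(traj.times[idx], traj.states[:, idx, :], traj.meta)
    return find_limit_cycle(tail)


@pytest.fixture(scope="session")
def sl_small_floquet(sl_small_cycle, sl_small_params):
    return compute_monodromy(sl_small_cycle, sl_small_params, n_steps=768)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
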