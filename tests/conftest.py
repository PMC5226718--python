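"""Shared fixtures.

Spiking ensembles are expensive, so the ones used by several tests
(the multistable lambda = 50 forced/free ensembles, the bistable
lambda = 15 ensemble, and a reduced-network symmetric ensemble) are
session-scoped and simulated once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wagernet.meanfield import MeanFieldParams
from wagernet.network import build_network
from wagernet.params import NetworkSpec
from wagernet.trials import DecisionParams, run_ensemble


@pytest.fixture(scope="session")
def mf_params() -> MeanFieldParams:
    return MeanFieldParams.from_network()


@pytest.fixture(scope="session")
def full_network():
    return build_network()


@pytest.fixture(scope="session")
def small_network():
    """200-neuron network with recurrent conductances rescaled to
    preserve total drive; used where per-trial cost matters more than
    finite-size realism."""
    return build_network(NetworkSpec(N=200, scale_recurrent=True))


@pytest.fixture(scope="session")
def forced_l50(full_network) -> pd.DataFrame:
    """Forced-choice ensemble at lambda = 50 Hz over a reduced
    delta-lambda x duration grid (17 trials per condition; together
    with the free-choice twin this exceeds 200 trials at lambda=50)."""
    conds = [dict(lam=50.0, dlam=d, duration=dur, free_choice=False)
             for d in (0.0, 8.0, 16.0) for dur in (300.0, 500.0)]
    return run_ensemble(conds, n_trials=17, base_seed=5000,
                        network=full_network)


@pytest.fixture(scope="session")
def free_l50(full_network) -> pd.DataFrame:
    """Free-choice ensemble matched to :func:`forced_l50`."""
    conds = [dict(lam=50.0, dlam=d, duration=dur, free_choice=True)
             for d in (0.0, 8.0, 16.0) for dur in (300.0, 500.0)]
    return run_ensemble(conds, n_trials=17, base_seed=9000,
                        network=full_network)


@pytest.fixture(scope="session")
def forced_l15(full_network) -> pd.DataFrame:
    """Bistable-regime ensemble: lambda = 15 Hz, threshold 24 Hz."""
    conds = [dict(lam=15.0, dlam=7.0, duration=dur, free_choice=False)
             for dur in (300.0, 500.0)]
    return run_ensemble(conds, n_trials=25, base_seed=13000,
                        network=full_network,
                        params=DecisionParams(theta=24.0))


@pytest.fixture(scope="session")
def symmetric_small(full_network) -> pd.DataFrame:
    """Full-network ensemble at delta_lambda = 0 with a shortened
    post-stimulus period, for choice-symmetry statistics (100
    trials)."""
    conds = [dict(lam=50.0, dlam=0.0, duration=100.0, free_choice=False)]
    return run_ensemble(conds, n_trials=100, base_seed=77,
                        network=full_network,
                        protocol_overrides=dict(post_sure_duration=400.0))


@pytest.fixture(scope="session")
def l50_landscape(mf_params):
    """Stimulus-condition attractor landscape at lambda = 50 Hz with
    basin boundaries of both decision attractors (8 rays each)."""
    from wagernet.meanfield import basin_boundary, enumerate_attractors

    land = enumerate_attractors(mf_params, 50.0, 0.0, "stimulus")
    fp_L = land.of_class("decision_L")
    fp_R = land.of_class("decision_R")
    pts_L = basin_boundary(mf_params, land, fp_L, n_rays=8)
    pts_R = basin_boundary(mf_params, land, fp_R, n_rays=8)
    return {"land": land, "fp_L": fp_L, "fp_R": fp_R,
            "pts_L": pts_L, "pts_R": pts_R}


def make_trial_table(**columns) -> pd.DataFrame:
    """Synthetic trial table with the run_ensemble schema."""
    n = len(next(iter(columns.values())))
    base = {
        "lam": np.full(n, 50.0),
        "dlam": np.zeros(n),
        "duration": np.full(n, 500.0),
        "free_choice": np.ones(n, dtype=bool),
        "seed": np.arange(n),
        "early_choice": ["L"] * n,
        "final_choice": ["L"] * n,
        "decision_time": np.full(n, 300.0),
        "rate_L": np.full(n, 20.0),
        "rate_R": np.full(n, 5.0),
        "rate_S_mean": np.full(n, 2.0),
        "change_of_mind": np.zeros(n, dtype=bool),
        "correct": np.ones(n, dtype=bool),
    }
    base.update(columns)
    return pd.DataFrame(base)
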