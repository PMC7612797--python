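import numpy as np
import pytest

from mrtrust.agent import AgentParams, Engine
from mrtrust.cohort import simulate_dyad
from mrtrust.estimation import (
    ParameterGrid,
    fit_subject,
    per_choice_likelihood,
    trajectory_choice_probs,
    trajectory_nll,
)


GEN = AgentParams(0.0, 0.6, 0, 1, 0.0, 0, 1.0, "investor")
TRUSTEE = AgentParams(0.4, 1.0, 0, 1, 0.0, 0, 1.0, "trustee")


def test_uniform_policy_nll_closed_form():
    """Ten uniform choices give nll = -10 log(0.2) and a per-choice
    geometric-mean likelihood of exactly chance (0.2)."""
    nll = -10 * np.log(0.2)
    assert nll == pytest.approx(16.094, abs=1e-3)
    assert per_choice_likelihood(nll, 10) == pytest.approx(0.2)


def test_nll_consistent_with_choice_probs(sample_history):
    params = AgentParams(0.0, 0.8, 0, 1, 0.0, 0, 0.5, "investor")
    probs = trajectory_choice_probs(sample_history, params)
    nll = trajectory_nll(sample_history, params)
    assert nll == pytest.approx(float(-np.log(probs).sum()))
    assert len(probs) == 10
    assert ((probs > 0) & (probs <= 1)).all()


def test_singleton_grid_returns_that_point(sample_history):
    grid = ParameterGrid(alpha=(0.4,), omega=(1.2,), k=(1,), planning=(2,),
                         zeta=(0.25,), q=(2,), beta=(0.5,))
    res = fit_subject(sample_history, grid)
    assert res.best_params.astuple() == (0.4, 1.2, 1, 2, 0.25, 2, 0.5)
    assert res.ties == 1
    assert res.grid_size == 1
    assert res.per_choice_likelihood == pytest.approx(np.exp(-res.nll / 10))


def test_refit_with_generating_point_in_grid_recovers_it():
    h = simulate_dyad(GEN, TRUSTEE, 1)
    grid = ParameterGrid(alpha=(GEN.alpha,), omega=(GEN.omega,), k=(GEN.k,),
                         planning=(GEN.planning,), zeta=(GEN.zeta,), q=(GEN.q,),
                         beta=(GEN.beta,))
    res = fit_subject(h, grid)
    assert res.best_params == GEN


def test_argmin_contract_and_order_invariance(sample_history):
    grid = ParameterGrid(alpha=(0.0,), omega=(0.4, 1.0, 1.8), k=(0,), planning=(1,),
                         zeta=(0.0,), q=(0,), beta=(0.25, 1.0))
    res = fit_subject(sample_history, grid, keep_nll=True)
    assert res.nll == pytest.approx(res.nll_by_point.min())
    # order invariance: evaluating points independently gives the same values
    for params, nll in zip(grid.points(), res.nll_by_point):
        assert trajectory_nll(sample_history, params) == pytest.approx(nll, abs=1e-9)


def test_generating_params_beat_distant_point_usually():
    """On deterministic (high beta) play the generating parameter vector has
    lower nll than a far-away grid point for most seeds."""
    distant = AgentParams(1.0, 1.8, 0, 1, 0.0, 0, 0.25, "investor")
    wins = 0
    n = 20
    eng = Engine()
    for seed in range(n):
        h = simulate_dyad(GEN, TRUSTEE, seed, engine=eng)
        if trajectory_nll(h, GEN, eng) <= trajectory_nll(h, distant, eng):
            wins += 1
    assert wins >= 0.75 * n


def test_myopic_fast_grid_matches_general_path(sample_history):
    """The vectorised k=0, P=1 evaluation must agree with the generic engine
    point by point."""
    grid = ParameterGrid(alpha=(0.0, 1.0), omega=(0.4, 1.0, 1.8), k=(0,),
                         planning=(1,), zeta=(0.0, 0.5), q=(0, 2), beta=(0.25, 1.0))
    res = fit_subject(sample_history, grid, keep_nll=True)
    eng = Engine()
    for params, fast_nll in zip(grid.points(), res.nll_by_point):
        slow = trajectory_nll(sample_history, params, eng)
        assert slow == pytest.approx(fast_nll, abs=1e-9), params


def test_empty_grid_rejected(sample_history):
    with pytest.raises(ValueError):
        fit_subject(sample_history, ParameterGrid(alpha=()))
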