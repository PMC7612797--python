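import numpy as np
import pytest

from mrtrust.agent import (
    AgentParams,
    BETA_GRID,
    BeliefState,
    Engine,
    ZETA_GRID,
    initial_beliefs,
    irritation_event,
    irritation_prior,
    update_irritation,
)
from mrtrust.cohort import simulate_dyad


# -- irritation dynamics ----------------------------------------------------


@pytest.mark.parametrize(
    "w,zeta,event,expected",
    [
        (0.25, 0.25, "escalate", 0.50),
        (0.75, 0.75, "escalate", 1.00),
        (0.50, 0.25, "deescalate", 0.25),
        (0.30, 0.0, "escalate", 0.30),
        (0.40, 0.25, "none", 0.40),
    ],
)
def test_update_irritation(w, zeta, event, expected):
    assert update_irritation(w, zeta, event) == pytest.approx(expected)


def test_irritation_weight_respects_cap():
    """n consecutive escalations give w = min(1, n * zeta)."""
    for zeta in ZETA_GRID:
        w = 0.0
        for n in range(1, 8):
            w = update_irritation(w, zeta, "escalate")
            assert w == pytest.approx(min(1.0, n * zeta))


def test_irritation_event_predicate():
    assert irritation_event(0.0, 5.0, 0.0) == "escalate"
    assert irritation_event(5.0, 5.0, 0.5) == "deescalate"  # at the mean
    assert irritation_event(7.0, 5.0, 0.0) == "none"  # nothing to undo


def test_irritation_priors_are_ordered_distributions():
    rows = [np.array(irritation_prior(q)) for q in range(5)]
    assert np.allclose(rows[0], [1, 0, 0, 0, 0])  # "never irritable"
    for row in rows:
        assert row.sum() == pytest.approx(1.0)
        assert (row >= 0).all()
    # strictly increasing first-order stochastic dominance in q
    cdfs = [np.cumsum(r) for r in rows]
    for lo, hi in zip(cdfs, cdfs[1:]):
        assert (hi[:-1] < lo[:-1] + 1e-12).all()
        assert (hi[:-1] < lo[:-1]).any()


# -- policies ---------------------------------------------------------------


def _params(**kw):
    base = dict(alpha=0.0, omega=1.0, k=0, planning=1, zeta=0.0, q=0, beta=1.0,
                role="investor")
    base.update(kw)
    return AgentParams(**base)


def test_policies_are_probability_vectors(engine):
    for k, p in [(0, 1), (1, 2), (0, 2)]:
        params = _params(k=k, planning=p, q=2, zeta=0.25)
        b = initial_beliefs(params)
        pol = engine.investor_policy(params, b, 10, 0.3)
        assert pol.sum() == pytest.approx(1.0, abs=1e-12)
        assert (pol >= 0).all()
        tp = _params(k=0, role="trustee", alpha=0.4)
        bt = initial_beliefs(tp)
        for a_idx in range(5):
            polt = engine.trustee_policy(tp, bt, a_idx, 10, 0.25)
            assert polt.sum() == pytest.approx(1.0, abs=1e-12)
            assert (polt >= 0).all()


def test_level_minus1_investor_keeps_everything(engine):
    """The non-mentalizing investor expects nothing back, so the modal
    action is invest 0 for any omega > 0."""
    for omega in (0.4, 1.0, 1.8):
        params = _params(omega=omega, k=-1)
        pol = engine.investor_policy(params, None, 10, 0.0)
        assert int(np.argmax(pol)) == 0


def test_flat_q_gives_uniform_policy(engine):
    params = _params()
    pol = engine.investor_policy_from_q(params, np.zeros(5), 0.0)
    assert np.allclose(pol, 0.2)


def test_effective_policy_is_convex_mixture(engine):
    params = _params(q=2, zeta=0.25)
    b = initial_beliefs(params)
    normal = engine.investor_policy(params, b, 10, 0.0)
    irritated = engine._irr_investor_policy(params)
    for w in (0.0, 0.25, 1.0):
        eff = engine.investor_policy(params, b, 10, w)
        assert np.allclose(eff, (1 - w) * normal + w * irritated, atol=1e-12)


def test_higher_beta_concentrates_policy(engine):
    q = np.array([1.0, 0.5, 0.0, -0.5, 2.0])
    masses = []
    for beta in sorted(BETA_GRID):
        pol = engine.investor_policy_from_q(_params(beta=beta), q, 0.0)
        masses.append(pol.max())
    assert all(b >= a for a, b in zip(masses, masses[1:]))


# -- belief updating --------------------------------------------------------


def test_uninformative_bins_skip_belief_update(engine):
    params = _params(q=2)
    b = initial_beliefs(params)
    for a_idx in (0, 1):  # invest 0 and invest 5
        b2 = engine.advance_investor(params, b, a_idx, 0, 10)
        assert b2.partner_alpha_belief == b.partner_alpha_belief
        assert b2.partner_zeta_belief == b.partner_zeta_belief


def test_equal_split_return_raises_guilt_posterior(engine):
    """After invest 10 and an equal-split return of 10, the posterior on a
    fully guilt-averse trustee must strictly increase."""
    params = _params()
    b = initial_beliefs(params)
    b2 = engine.advance_investor(params, b, 2, 2, 10)  # invest 10, return 10
    assert b2.partner_alpha_belief[2] > b.partner_alpha_belief[2]
    assert sum(b2.partner_alpha_belief) == pytest.approx(1.0, abs=1e-12)


def test_repeated_fair_returns_monotonically_increase_guilt_posterior(engine):
    params = _params()
    b = initial_beliefs(params)
    masses = [b.partner_alpha_belief[2]]
    r = 10
    for _ in range(5):
        b = engine.advance_investor(params, b, 2, 2, r)
        r -= 1
        masses.append(b.partner_alpha_belief[2])
    assert all(m2 > m1 for m1, m2 in zip(masses, masses[1:]))


def test_zero_return_after_full_investment_escalates(engine):
    """A cooperative partner model expects a positive return after invest 20,
    so a zero return is an irritation event."""
    params = _params(zeta=0.5)
    b = initial_beliefs(params)
    # make the model cooperative: certain the trustee is guilt-averse
    b = BeliefState((0.0, 0.0, 1.0), b.partner_zeta_belief,
                    b.partner_irritation_weights, 0.0, b.partner)
    pr = engine.predictive_return_dist(params, b, 4, 10)
    from mrtrust.game import return_amounts
    assert float(pr @ np.array(return_amounts(20), dtype=float)) > 0
    b2 = engine.advance_investor(params, b, 4, 0, 10)  # invest 20, return 0
    assert b2.own_irritation_weight == pytest.approx(0.5)


def test_zeta_zero_agents_never_become_irritated():
    inv = _params(zeta=0.0, omega=1.8, beta=1.0)
    tr = AgentParams(0.0, 1.0, 0, 1, 0.0, 0, 1.0, "trustee")  # selfish trustee
    eng = Engine()
    b = initial_beliefs(inv)
    r = 10
    for a_idx, f_idx in [(4, 0), (4, 0), (3, 0), (2, 0)]:  # repeated betrayals
        b = eng.advance_investor(inv, b, a_idx, f_idx, r)
        r -= 1
        assert b.own_irritation_weight == 0.0


def test_simulated_dyads_are_seed_deterministic():
    inv = _params(k=0, planning=1, zeta=0.25, q=2, beta=0.5)
    tr = AgentParams(0.4, 1.0, 0, 1, 0.25, 0, 1.0, "trustee")
    h1 = simulate_dyad(inv, tr, 123)
    h2 = simulate_dyad(inv, tr, 123)
    assert [(r.a_i, r.a_t) for r in h1] == [(r.a_i, r.a_t) for r in h2]
    h3 = simulate_dyad(inv, tr, 124)
    assert len(h3) == 10
    for rec in h3:
        if rec.a_i == 0:
            assert rec.a_t == 0
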