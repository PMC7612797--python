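import numpy as np
import pytest
from scipy import stats as sps

from mrtrust.agent import AgentParams
from mrtrust.cohort import (
    CohortConfig,
    LinkCoefficients,
    generate_cohort,
    simulate_dyad,
    summarize_ensemble,
)


@pytest.fixture(scope="module")
def small_cohort():
    cfg = CohortConfig(n=60, seed=11)
    return generate_cohort(cfg)


def test_cohort_size_and_round_count(small_cohort):
    assert len(small_cohort) == 60
    for rec in small_cohort:
        assert len(rec.trajectory) == 10
        rec.trajectory.validate()
        assert rec.true_params is not None
        assert 14 <= rec.age <= 25
        assert rec.sex in (0, 1)


def test_cohort_is_seed_deterministic():
    cfg = CohortConfig(n=12, seed=5)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    for ra, rb in zip(a, b):
        assert [(x.a_i, x.a_t) for x in ra.trajectory] == [(x.a_i, x.a_t) for x in rb.trajectory]
        assert ra.true_params == rb.true_params
        assert ra.age == rb.age and ra.iq == rb.iq


def test_age_link_produces_negative_age_omega_association():
    """Strong negative age->omega link shows up as negative Kendall tau."""
    cfg = CohortConfig(n=500, seed=3)
    cfg.links = LinkCoefficients(omega_age=-2.0, omega_iq=0.0, omega_sex=0.0,
                                 omega_ses=0.0, omega_ses2=0.0, omega_noise=0.5)
    rng = np.random.default_rng(cfg.seed)
    from mrtrust.cohort import draw_parameters, generate_demographics

    demo = generate_demographics(cfg, rng)
    params = draw_parameters(demo, cfg, rng)
    tau, _ = sps.kendalltau(demo["age"], [p.omega for p in params])
    assert tau < -0.5


def test_zero_links_remove_demographic_association():
    cfg = CohortConfig(n=500, seed=4)
    cfg.links = cfg.links.zeroed()
    rng = np.random.default_rng(cfg.seed)
    from mrtrust.cohort import draw_parameters, generate_demographics

    demo = generate_demographics(cfg, rng)
    params = draw_parameters(demo, cfg, rng)
    for col in ("age", "iq", "ses", "sex"):
        tau, p = sps.kendalltau(demo[col], [p_.omega for p_ in params])
        assert abs(tau) < 0.1


def test_summarize_ensemble(small_cohort):
    out = summarize_ensemble(small_cohort)
    per_round = out["per_round"]
    assert len(per_round) == 10
    assert (per_round["invest_mean"] <= 20).all()
    assert per_round["invest_sem"].notna().all()
    quint = out["quintiles"]
    np.testing.assert_allclose(quint.sum(axis=1), 1.0)
    assert out["by_omega"] is not None


def test_summarize_single_record_has_missing_sem(small_cohort):
    out = summarize_ensemble(small_cohort[:1])
    assert out["per_round"]["invest_sem"].isna().all()


def test_high_beta_risk_averse_myopic_investor_stays_low():
    """A deterministic, strongly risk-averse non-planner keeps its endowment."""
    inv = AgentParams(0.0, 1.8, 0, 1, 0.0, 0, 1.0, "investor")
    tr = AgentParams(1.0, 1.0, 0, 1, 0.0, 0, 1.0, "trustee")
    h = simulate_dyad(inv, tr, 99)
    assert np.mean([r.a_i for r in h]) <= 5.0
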