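import numpy as np
import pytest

from mrtrust.agent import AgentParams, Engine
from mrtrust.cohort import simulate_dyad


@pytest.fixture(scope="session")
def engine():
    return Engine()


@pytest.fixture(scope="session")
def sample_history():
    """A mixed trajectory from a mentalizing investor vs a mildly irritable
    cooperative trustee."""
    inv = AgentParams(0.0, 0.8, 1, 2, 0.25, 2, 1.0, "investor")
    tr = AgentParams(0.4, 1.0, 0, 1, 0.25, 0, 0.5, "trustee")
    return simulate_dyad(inv, tr, 7)


def random_belief_state(rng: np.random.Generator, nested: bool):
    """A random valid belief state (Dirichlet vectors, lattice weights)."""
    from mrtrust.agent import BeliefState, ZETA_GRID

    def dirichlet(n):
        v = rng.dirichlet(np.ones(n))
        return tuple(float(x) for x in v / v.sum())

    partner = None
    if nested:
        partner = BeliefState(
            partner_alpha_belief=dirichlet(3),
            partner_zeta_belief=dirichlet(5),
            partner_irritation_weights=tuple(
                float(rng.choice([0.0, z, min(1.0, 2 * z)])) for z in ZETA_GRID
            ),
            own_irritation_weight=0.0,
        )
    return BeliefState(
        partner_alpha_belief=dirichlet(3),
        partner_zeta_belief=dirichlet(5),
        partner_irritation_weights=tuple(
            float(rng.choice([0.0, z, min(1.0, 2 * z)])) for z in ZETA_GRID
        ),
        own_irritation_weight=float(rng.choice([0.0, 0.25, 0.5])),
        partner=partner,
    )


def belief_to_dict(b):
    if b is None:
        return None
    return dict(
        pa=list(b.partner_alpha_belief),
        pz=list(b.partner_zeta_belief),
        wp=list(b.partner_irritation_weights),
        w=b.own_irritation_weight,
        partner=belief_to_dict(b.partner),
    )
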