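"""Synthetic dyads and cohorts.

The study population this emulates: adolescents and young adults (ages
14-25, balanced sex) playing ten rounds of the trust game as investors
against an adult trustee.  The trustee here is a model-based I-POMDP agent
with a configurable parameter distribution — a stand-in for the original
experiment's database-driven algorithm, not a reproduction of it.

Demographic structure is injected through link functions: by default risk
aversion (omega) decreases with age and IQ, is higher in females, and has a
linear-plus-quadratic relation to socio-economic adversity; guilt (alpha) is
shifted upward in females.  All links are configurable, including off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .agent import (
    AgentParams,
    BETA_GRID,
    DEFAULT_CONFIG,
    Engine,
    ModelConfig,
    initial_beliefs,
)
from .game import History, INVESTOR_BINS, N_ROUNDS, return_amounts
from .preferences import ALPHA_GRID, OMEGA_GRID


@dataclass
class SubjectRecord:
    """One synthetic participant: demographics, trajectory, parameters."""

    subject_id: str
    age: float
    sex: int  # male = 0, female = 1
    iq: float
    ses: float  # adversity score; higher = more adverse
    trajectory: Optional[History] = None
    true_params: Optional[AgentParams] = None
    trustee_params: Optional[AgentParams] = None
    fitted_params: Optional[AgentParams] = None

    @property
    def total_investment(self) -> int:
        return self.trajectory.total_investment()

    @property
    def total_earnings(self) -> int:
        return self.trajectory.total_earnings()


def simulate_dyad(
    investor: AgentParams,
    trustee: AgentParams,
    seed,
    config: ModelConfig = DEFAULT_CONFIG,
    n_rounds: int = N_ROUNDS,
    engine: Optional[Engine] = None,
) -> History:
    """Play one dyad; both agents sample from their effective policies and
    update beliefs/irritation each round.  Deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    eng = engine if engine is not None else Engine(config)
    inv = investor if investor.role == "investor" else None
    if inv is None:
        raise ValueError("first agent must have role 'investor'")
    if trustee.role != "trustee":
        raise ValueError("second agent must have role 'trustee'")
    b_inv = initial_beliefs(investor, eng.config)
    b_tr = initial_beliefs(trustee, eng.config)
    hist = History()
    for t in range(n_rounds):
        r = n_rounds - t
        pol_i = eng.investor_policy(investor, b_inv, r, b_inv.own_irritation_weight)
        a_idx = int(rng.choice(len(pol_i), p=pol_i))
        pol_t = eng.trustee_policy(trustee, b_tr, a_idx, r, b_tr.own_irritation_weight)
        f_idx = int(rng.choice(len(pol_t), p=pol_t))
        a_i = INVESTOR_BINS[a_idx]
        a_t = return_amounts(a_i)[f_idx]
        hist.append(a_i, a_t)
        b_inv = eng.advance_investor(investor, b_inv, a_idx, f_idx, r)
        b_tr = eng.advance_trustee(trustee, b_tr, a_idx, f_idx, r)
    return hist


# --------------------------------------------------------------------------
# Cohort generation


@dataclass
class LinkCoefficients:
    """Latent-index links from z-scored demographics to parameters.

    omega: latent grid index = ``omega_base + sum(coef * covariate) + noise``
    rounded and clamped to the 8-point grid.  alpha: ordered-threshold latent
    ``alpha_sex * sex + noise`` cut at ``alpha_thresholds``.
    """

    # omega spans the full grid (every risk-aversion setting occurs in both
    # sexes), decreases with age and IQ, is higher in females, and has a
    # linear-plus-quadratic relation to adversity
    omega_base: float = 3.5
    omega_age: float = -1.0
    omega_iq: float = -1.0
    omega_sex: float = 1.0  # female-coded 1: higher risk aversion in females
    omega_ses: float = 0.5
    omega_ses2: float = -0.3
    omega_noise: float = 1.5
    # guilt: females more often inequality-averse; most subjects carry no
    # guilt and full guilt is rare
    alpha_sex: float = 1.0
    alpha_noise: float = 1.0
    alpha_thresholds: tuple[float, float] = (1.7, 2.9)

    def zeroed(self) -> "LinkCoefficients":
        return LinkCoefficients(
            omega_base=self.omega_base,
            omega_age=0.0, omega_iq=0.0, omega_sex=0.0,
            omega_ses=0.0, omega_ses2=0.0,
            omega_noise=self.omega_noise,
            alpha_sex=0.0, alpha_noise=self.alpha_noise,
            alpha_thresholds=self.alpha_thresholds,
        )


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    n: int = 784
    age_range: tuple[float, float] = (14.0, 25.0)
    iq_mean: float = 100.0
    iq_sd: float = 15.0
    links: LinkCoefficients = field(default_factory=LinkCoefficients)
    #: distributions over the remaining investor parameters (value -> prob).
    #: Myopic non-mentalizers keep cohort simulation tractable; the beta mix
    #: is weighted toward stochastic play, which reproduces per-choice
    #: likelihoods in the observed range rather than degenerate all-or-none
    #: trajectories.
    k_dist: dict = field(default_factory=lambda: {0: 1.0})
    p_dist: dict = field(default_factory=lambda: {1: 1.0})
    zeta_dist: dict = field(default_factory=lambda: {0.0: 0.8, 0.25: 0.2})
    q_dist: dict = field(default_factory=lambda: {0: 0.8, 1: 0.2})
    beta_dist: dict = field(
        default_factory=lambda: {0.25: 0.3, 1 / 3: 0.3, 0.5: 0.3, 1.0: 0.1}
    )
    #: trustee parameter distribution (the model-based stand-in partner);
    #: cooperative, guilt-averse trustees emulate the healthy adult play the
    #: original experiment's algorithmic partner was built from
    trustee_alpha_dist: dict = field(default_factory=lambda: {0.4: 0.5, 1.0: 0.5})
    trustee_zeta_dist: dict = field(default_factory=lambda: {0.0: 1.0})
    trustee_beta: float = 1.0
    trustee_k: int = 0
    trustee_p: int = 1
    trustee_q: int = 0
    seed: int = 0


def _draw(rng: np.random.Generator, dist: dict):
    keys = list(dist.keys())
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs /= probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _nearest_grid(value: float, grid) -> float:
    grid = np.asarray(grid, dtype=float)
    return float(grid[int(np.argmin(np.abs(grid - value)))])


def _zscore(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def draw_parameters(
    demographics: pd.DataFrame, config: CohortConfig, rng: np.random.Generator
) -> list[AgentParams]:
    """Assign true investor parameters from demographics via the links."""
    links = config.links
    z_age = _zscore(demographics["age"].to_numpy(float))
    z_iq = _zscore(demographics["iq"].to_numpy(float))
    z_ses = _zscore(demographics["ses"].to_numpy(float))
    sex = demographics["sex"].to_numpy(float)
    idx_latent = (
        links.omega_base
        + links.omega_age * z_age
        + links.omega_iq * z_iq
        + links.omega_sex * sex
        + links.omega_ses * z_ses
        + links.omega_ses2 * (z_ses**2 - 1.0)
        + links.omega_noise * rng.standard_normal(len(demographics))
    )
    omega_idx = np.clip(np.rint(idx_latent), 0, len(OMEGA_GRID) - 1).astype(int)
    alpha_latent = links.alpha_sex * sex + links.alpha_noise * rng.standard_normal(
        len(demographics)
    )
    lo, hi = links.alpha_thresholds
    alpha_idx = np.where(alpha_latent < lo, 0, np.where(alpha_latent < hi, 1, 2))
    params = []
    for i in range(len(demographics)):
        params.append(
            AgentParams(
                alpha=ALPHA_GRID[alpha_idx[i]],
                omega=OMEGA_GRID[omega_idx[i]],
                k=int(_draw(rng, config.k_dist)),
                planning=int(_draw(rng, config.p_dist)),
                zeta=float(_draw(rng, config.zeta_dist)),
                q=int(_draw(rng, config.q_dist)),
                beta=_nearest_grid(float(_draw(rng, config.beta_dist)), BETA_GRID),
                role="investor",
            ).validate()
        )
    return params


def draw_trustee(config: CohortConfig, rng: np.random.Generator) -> AgentParams:
    return AgentParams(
        alpha=float(_draw(rng, config.trustee_alpha_dist)),
        omega=1.0,
        k=config.trustee_k,
        planning=config.trustee_p,
        zeta=float(_draw(rng, config.trustee_zeta_dist)),
        q=config.trustee_q,
        beta=config.trustee_beta,
        role="trustee",
    ).validate()


def generate_demographics(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n
    lo, hi = config.age_range
    sex = np.zeros(n, dtype=int)
    sex[: n // 2] = 1
    rng.shuffle(sex)  # balanced sexes
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "age": rng.uniform(lo, hi, size=n),
            "sex": sex,
            "iq": rng.normal(config.iq_mean, config.iq_sd, size=n),
            "ses": rng.standard_normal(n),
        }
    )


def generate_cohort(
    config: CohortConfig, model_config: ModelConfig = DEFAULT_CONFIG
) -> list[SubjectRecord]:
    """Draw demographics, assign parameters, and simulate one dyad each."""
    rng = np.random.default_rng(config.seed)
    demo = generate_demographics(config, rng)
    params = draw_parameters(demo, config, rng)
    engine = Engine(model_config)
    records = []
    for i, row in demo.iterrows():
        engine.clear()  # belief states rarely recur across dyads; cap memory
        trustee = draw_trustee(config, rng)
        hist = simulate_dyad(
            params[i], trustee, rng.integers(0, 2**31 - 1), engine=engine
        )
        records.append(
            SubjectRecord(
                subject_id=row["subject_id"],
                age=float(row["age"]),
                sex=int(row["sex"]),
                iq=float(row["iq"]),
                ses=float(row["ses"]),
                trajectory=hist,
                true_params=params[i],
                trustee_params=trustee,
            )
        )
    return records


# --------------------------------------------------------------------------
# Ensemble summaries


def summarize_ensemble(records: list[SubjectRecord]) -> dict[str, pd.DataFrame]:
    """Per-round mean +/- SEM of investments and repayments, mean investment
    by risk aversion, and earnings-quintile shares by sex."""
    if not records:
        raise ValueError("empty ensemble")
    rows = []
    for rec in records:
        for rr in rec.trajectory:
            rows.append((rec.subject_id, rr.round_index, rr.a_i, rr.a_t))
    long = pd.DataFrame(rows, columns=["subject_id", "round", "investment", "repayment"])

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else np.nan

    per_round = long.groupby("round").agg(
        invest_mean=("investment", "mean"),
        invest_sem=("investment", _sem),
        repay_mean=("repayment", "mean"),
        repay_sem=("repayment", _sem),
    )

    by_omega = None
    if all(r.true_params is not None for r in records):
        df = pd.DataFrame(
            {
                "omega": [r.true_params.omega for r in records],
                "total_investment": [r.total_investment for r in records],
            }
        )
        by_omega = df.groupby("omega")["total_investment"].agg(["mean", "std", "count"])

    earn = pd.DataFrame(
        {
            "sex": [r.sex for r in records],
            "earnings": [r.total_earnings for r in records],
        }
    )
    # quintiles on average ranks so ties land in a deterministic bin
    ranks = earn["earnings"].rank(method="average")
    earn["quintile"] = np.minimum((5 * (ranks - 0.5) / len(earn)).astype(int) + 1, 5)
    quint = (
        earn.groupby(["sex", "quintile"]).size().unstack(fill_value=0).astype(float)
    )
    quint = quint.div(quint.sum(axis=1), axis=0)

    return {"per_round": per_round, "by_omega": by_omega, "quintiles": quint}
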