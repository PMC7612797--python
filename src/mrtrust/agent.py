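"""The interactive (I-POMDP) agent for the multi-round trust game.

An agent is described by seven parameters: guilt ``alpha``, risk aversion
``omega``, theory-of-mind level ``k``, planning horizon ``P``, irritability
``zeta``, irritation awareness ``q`` and inverse temperature ``beta``.  A
level-k agent models its partner exclusively at level k-1, maintains discrete
Bayesian beliefs over the partner's guilt and irritability, tracks a mixture
weight on a punitive "irritated" policy for itself and (per candidate
irritability) for the partner, plans by finite-horizon expectimax with beliefs
updated along each branch, and chooses through a logistic softmax.

The irritated policy is the non-mentalizing (level -1) myopic policy with
guilt removed: the investor keeps everything, the trustee returns nothing.

All recursion is routed through an :class:`Engine`, which memoizes policy and
value computations keyed by parameters and a rounded belief signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal, Optional

import numpy as np

from .game import INVESTOR_BINS, N_ACTIONS, return_amounts
from .preferences import (
    ALPHA_GRID,
    OMEGA_GRID,
    InvalidParamsError,
    _investor_utility_raw,
    _trustee_utility_raw,
)

K_GRID = (0, 1, 2, 3, 4)
P_GRID = (1, 2, 3, 4)
ZETA_GRID = (0.0, 0.25, 0.5, 0.75, 1.0)
Q_GRID = (0, 1, 2, 3, 4)
BETA_GRID = (1 / 4, 1 / 3, 1 / 2, 1.0)

Role = Literal["investor", "trustee"]
Event = Literal["escalate", "deescalate", "none"]

_INVEST = np.array(INVESTOR_BINS, dtype=float)
#: AMT[a, f] — coin amount of fraction index f at investment bin index a.
_AMT = np.array([return_amounts(a) for a in INVESTOR_BINS], dtype=float)
_EPS = 1e-9
_SIG_DECIMALS = 12


@dataclass(frozen=True, eq=False)
class AgentParams:
    """The seven-parameter vector plus role.

    ``k == -1`` is the internal non-mentalizing level used for irritated play
    and at the base of the partner-model recursion; it is not a fit value.
    """

    alpha: float
    omega: float
    k: int
    planning: int
    zeta: float
    q: int
    beta: float
    role: Role = "investor"

    # hand-rolled equality/hash with a cached hash: these objects key every
    # memo-table lookup in the engine, so this is hot
    def _key(self) -> tuple:
        return (self.alpha, self.omega, self.k, self.planning, self.zeta,
                self.q, self.beta, self.role)

    def __eq__(self, other):
        if not isinstance(other, AgentParams):
            return NotImplemented
        return self._key() == other._key()

    def __hash__(self) -> int:
        h = getattr(self, "_hash", None)
        if h is None:
            h = hash(self._key())
            object.__setattr__(self, "_hash", h)
        return h

    def validate(self) -> "AgentParams":
        for value, grid, name in (
            (self.alpha, ALPHA_GRID, "alpha"),
            (self.omega, OMEGA_GRID, "omega"),
            (self.k, K_GRID, "k"),
            (self.planning, P_GRID, "P"),
            (self.zeta, ZETA_GRID, "zeta"),
            (self.q, Q_GRID, "q"),
            (self.beta, BETA_GRID, "beta"),
        ):
            if not any(abs(value - g) < 1e-12 for g in grid):
                raise InvalidParamsError(f"{name}={value} not on grid {grid}")
        if self.role not in ("investor", "trustee"):
            raise InvalidParamsError(f"unknown role {self.role!r}")
        return self

    def astuple(self) -> tuple:
        return (self.alpha, self.omega, self.k, self.planning, self.zeta, self.q, self.beta)


def _flip(role: Role) -> Role:
    return "trustee" if role == "investor" else "investor"


_PARTNER_CACHE: dict = {}


def partner_params(params: AgentParams, alpha: float, zeta: float) -> AgentParams:
    """Parameters of a modelled partner candidate.

    The partner operates at level k-1 with the hypothesised guilt and
    irritability; all remaining parameters are copied from the agent (the
    agent assumes the partner shares its risk aversion, planning, awareness
    and temperature).
    """
    key = (params, alpha, zeta)
    hit = _PARTNER_CACHE.get(key)
    if hit is None:
        hit = replace(params, alpha=alpha, zeta=zeta, k=params.k - 1, role=_flip(params.role))
        if len(_PARTNER_CACHE) > 100_000:
            _PARTNER_CACHE.clear()
        _PARTNER_CACHE[key] = hit
    return hit


# --------------------------------------------------------------------------
# Beliefs and irritation dynamics


@dataclass(frozen=True)
class BeliefState:
    """Discrete beliefs about the partner plus irritation mixture weights.

    ``partner`` is the modelled partner's own belief state (present when the
    agent mentalizes at level >= 1); its ``own_irritation_weight`` is unused
    because candidate partner weights are tracked per candidate irritability
    in ``partner_irritation_weights``.
    """

    partner_alpha_belief: tuple[float, ...]
    partner_zeta_belief: tuple[float, ...]
    partner_irritation_weights: tuple[float, ...]
    own_irritation_weight: float = 0.0
    partner: Optional["BeliefState"] = None

    def sig(self) -> tuple:
        cached = getattr(self, "_sig", None)
        if cached is None:
            cached = (
                tuple(round(p, _SIG_DECIMALS) for p in self.partner_alpha_belief),
                tuple(round(p, _SIG_DECIMALS) for p in self.partner_zeta_belief),
                tuple(round(w, _SIG_DECIMALS) for w in self.partner_irritation_weights),
                round(self.own_irritation_weight, _SIG_DECIMALS),
                None if self.partner is None else self.partner.sig(),
            )
            object.__setattr__(self, "_sig", cached)
        return cached

    def check(self) -> None:
        for vec in (self.partner_alpha_belief, self.partner_zeta_belief):
            if abs(sum(vec) - 1.0) > 1e-12 or any(p < -1e-15 for p in vec):
                raise ValueError(f"belief vector {vec} is not a probability vector")
        for w in (*self.partner_irritation_weights, self.own_irritation_weight):
            if not -1e-15 <= w <= 1 + 1e-15:
                raise ValueError(f"irritation weight {w} outside [0, 1]")
        if self.partner is not None:
            self.partner.check()


_DEFAULT_Q_TOP = (0.0, 0.05, 0.10, 0.15, 0.70)


def default_q_priors() -> tuple[tuple[float, ...], ...]:
    """Prior over partner irritability for each awareness index q = 0..4.

    q=0 is a point mass on zeta=0 ("never irritable"); q=4 puts 70% on
    zeta=1 ("certainly irritable"); intermediate indices interpolate
    linearly, which makes the family strictly ordered by first-order
    stochastic dominance.
    """
    point = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    top = np.array(_DEFAULT_Q_TOP)
    rows = []
    for j in range(5):
        t = j / 4.0
        rows.append(tuple((1 - t) * point + t * top))
    return tuple(rows)


@dataclass(frozen=True)
class ModelConfig:
    """Tunable model structure: priors, predicate, lookahead mode."""

    q_priors: tuple[tuple[float, ...], ...] = field(default_factory=default_q_priors)
    alpha_prior: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    #: Bayes-update beliefs along planning branches (True = full I-POMDP
    #: semantics); irritation weights advance in either mode.
    branch_beliefs: bool = True
    #: Non-mentalizing investor assumption: partner returns nothing, or
    #: returns uniformly over the legal grid.
    level_neg1_investor: Literal["zero-return", "uniform-return"] = "zero-return"
    #: Optional override for the escalation test: f(observed, expectation) -> bool.
    escalate_if: Optional[Callable[[float, float], bool]] = None


DEFAULT_CONFIG = ModelConfig()


def irritation_prior(q_index: int, config: ModelConfig = DEFAULT_CONFIG) -> tuple[float, ...]:
    """Prior belief over the partner's irritability for awareness index q."""
    if q_index not in Q_GRID:
        raise InvalidParamsError(f"q={q_index} not on grid {Q_GRID}")
    return tuple(config.q_priors[q_index])


def update_irritation(w: float, zeta: float, event: Event) -> float:
    """Advance an irritated-policy mixture weight by one event.

    Escalations add ``zeta`` (capped at 1), de-escalations remove ``zeta``
    (floored at 0); ``none`` leaves the weight unchanged.
    """
    if event == "escalate":
        return min(1.0, w + zeta)
    if event == "deescalate":
        return max(0.0, w - zeta)
    if event == "none":
        return w
    raise ValueError(f"unknown irritation event {event!r}")


def irritation_event(
    observed: float, expectation: float, w: float, config: ModelConfig = DEFAULT_CONFIG
) -> Event:
    """Classify a partner action against the model expectation.

    Default predicate: escalate when the realized action falls strictly below
    the probability-weighted mean action under the current partner model;
    de-escalate when at or above it while irritated; otherwise nothing.
    """
    if config.escalate_if is not None:
        below = config.escalate_if(observed, expectation)
    else:
        below = observed < expectation - _EPS
    if below:
        return "escalate"
    return "deescalate" if w > 0 else "none"


def initial_beliefs(params: AgentParams, config: ModelConfig = DEFAULT_CONFIG) -> BeliefState:
    """Priors before the first round, nested down the mentalizing hierarchy."""
    partner = None
    if params.k >= 1:
        partner = initial_beliefs(partner_params(params, 0.0, 0.0), config)
    return BeliefState(
        partner_alpha_belief=tuple(config.alpha_prior),
        partner_zeta_belief=irritation_prior(params.q, config),
        partner_irritation_weights=(0.0,) * len(ZETA_GRID),
        own_irritation_weight=0.0,
        partner=partner,
    )


# --------------------------------------------------------------------------
# Engine


def _softmax(x: np.ndarray) -> np.ndarray:
    z = np.exp(x - x.max())
    return z / z.sum()


def _trustee_state_free(params: AgentParams) -> bool:
    """A level-0 trustee's plans never read its belief state: its level -1
    investor model is candidate-independent, so predictions, expectations and
    continuation values are all constants of (params, action, horizon)."""
    return params.role == "trustee" and params.k == 0


class Engine:
    """Memoized policy/value/belief computations for every mentalizing level."""

    def __init__(self, config: ModelConfig = DEFAULT_CONFIG):
        self.config = config
        self._cache: dict = {}
        self._u_tables: dict = {}
        #: set when a Bayes update met (numerically) zero total likelihood
        self.degenerate_evidence = False

    def clear(self) -> None:
        self._cache.clear()

    # -- utility tables ----------------------------------------------------

    def _u_inv(self, alpha: float, omega: float) -> np.ndarray:
        key = ("ui", alpha, omega)
        tab = self._u_tables.get(key)
        if tab is None:
            tab = np.array(
                [
                    [_investor_utility_raw(a, int(_AMT[ai, f]), alpha, omega) for f in range(5)]
                    for ai, a in enumerate(INVESTOR_BINS)
                ]
            )
            self._u_tables[key] = tab
        return tab

    def _u_tr(self, alpha_t: float) -> np.ndarray:
        key = ("ut", alpha_t)
        tab = self._u_tables.get(key)
        if tab is None:
            tab = np.array(
                [
                    [_trustee_utility_raw(a, int(_AMT[ai, f]), alpha_t) for f in range(5)]
                    for ai, a in enumerate(INVESTOR_BINS)
                ]
            )
            self._u_tables[key] = tab
        return tab

    def _irr_investor_policy(self, params: AgentParams) -> np.ndarray:
        """Punitive investor policy: myopic, guilt-free, partner ignored."""
        key = ("irr_i", params.beta, params.omega, self.config.level_neg1_investor)
        pol = self._u_tables.get(key)
        if pol is None:
            if self.config.level_neg1_investor == "zero-return":
                u = params.omega * (20.0 - _INVEST)
            else:  # uniform-return partner assumption
                u = self._u_inv(0.0, params.omega).mean(axis=1)
            pol = _softmax(params.beta * u)
            self._u_tables[key] = pol
        return pol

    def _irr_trustee_policy(self, params: AgentParams, a_idx: int) -> np.ndarray:
        """Punitive trustee policy: myopic softmax with guilt removed."""
        key = ("irr_t", params.beta, a_idx)
        pol = self._u_tables.get(key)
        if pol is None:
            pol = _softmax(params.beta * self._u_tr(0.0)[a_idx])
            self._u_tables[key] = pol
        return pol

    # -- investor side -----------------------------------------------------

    def investor_policy(
        self, params: AgentParams, beliefs: Optional[BeliefState], rounds_left: int, w: float
    ) -> np.ndarray:
        """Effective policy over the five investment bins."""
        irr = self._irr_investor_policy(params)
        if params.k < 0:
            return irr
        q = self.investor_q(params, beliefs, min(params.planning, rounds_left), rounds_left)
        normal = _softmax(params.beta * q)
        return (1.0 - w) * normal + w * irr

    def investor_q(
        self, params: AgentParams, beliefs: BeliefState, horizon: int, rounds_left: int
    ) -> np.ndarray:
        """Expectimax action values for a level>=0 investor."""
        horizon = min(horizon, rounds_left)
        key = ("iq", params, beliefs.sig(), horizon, rounds_left)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        u = self._u_inv(params.alpha, params.omega)
        q = np.empty(N_ACTIONS)
        for a_idx in range(N_ACTIONS):
            pr = self.predictive_return_dist(params, beliefs, a_idx, rounds_left)
            qa = float(pr @ u[a_idx])
            if horizon > 1 and rounds_left > 1:
                for f_idx in range(5):
                    if pr[f_idx] <= 1e-14:
                        continue
                    nxt = self.advance_investor(
                        params, beliefs, a_idx, f_idx, rounds_left,
                        update_own_w=True, branch=True,
                    )
                    qa += pr[f_idx] * self._investor_value(
                        params, nxt, horizon - 1, rounds_left - 1
                    )
            q[a_idx] = qa
        q.setflags(write=False)
        self._cache[key] = q
        return q

    def _investor_value(
        self, params: AgentParams, beliefs: BeliefState, horizon: int, rounds_left: int
    ) -> float:
        key = ("iv", params, beliefs.sig(), horizon, rounds_left)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        q = self.investor_q(params, beliefs, horizon, rounds_left)
        pol = self.investor_policy_from_q(params, q, beliefs.own_irritation_weight)
        val = float(pol @ q)
        self._cache[key] = val
        return val

    def investor_policy_from_q(self, params: AgentParams, q: np.ndarray, w: float) -> np.ndarray:
        normal = _softmax(params.beta * q)
        if w == 0.0:
            return normal
        return (1.0 - w) * normal + w * self._irr_investor_policy(params)

    def _trustee_policy_bank(
        self, params: AgentParams, beliefs: BeliefState, a_idx: int, rounds_left: int
    ) -> np.ndarray:
        """(3, 5, 5) array of the modelled trustee's effective policies for
        every (alpha_T, zeta_T) candidate at the tracked irritation weights.

        Columns whose candidate carries (numerically) zero belief mass are
        left at zero — they never contribute to a marginal or a posterior.
        """
        partner = beliefs.partner
        psig = None if partner is None else partner.sig()
        key = (
            "bank", params, psig, a_idx, rounds_left,
            beliefs.partner_irritation_weights,
            tuple(p > 1e-14 for p in beliefs.partner_alpha_belief),
            tuple(p > 1e-14 for p in beliefs.partner_zeta_belief),
        )
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        bank = np.zeros((len(ALPHA_GRID), len(ZETA_GRID), 5))
        for i, alpha_t in enumerate(ALPHA_GRID):
            if beliefs.partner_alpha_belief[i] <= 1e-14:
                continue
            for j, zeta_t in enumerate(ZETA_GRID):
                if beliefs.partner_zeta_belief[j] <= 1e-14:
                    continue
                bank[i, j] = self.trustee_policy(
                    partner_params(params, alpha_t, zeta_t),
                    partner,
                    a_idx,
                    rounds_left,
                    beliefs.partner_irritation_weights[j],
                )
        bank.setflags(write=False)
        self._cache[key] = bank
        return bank

    def predictive_return_dist(
        self, params: AgentParams, beliefs: BeliefState, a_idx: int, rounds_left: int
    ) -> np.ndarray:
        """Marginal model prediction of the trustee's return (fraction index),
        mixing over candidate guilt/irritability and tracked irritation."""
        key = ("prd", params, beliefs.sig(), a_idx, rounds_left)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        bank = self._trustee_policy_bank(params, beliefs, a_idx, rounds_left)
        acc = np.einsum(
            "i,j,ijf->f",
            np.asarray(beliefs.partner_alpha_belief),
            np.asarray(beliefs.partner_zeta_belief),
            bank,
        )
        acc = acc / acc.sum()
        acc.setflags(write=False)
        self._cache[key] = acc
        return acc

    def advance_investor(
        self,
        params: AgentParams,
        beliefs: BeliefState,
        a_idx: int,
        f_idx: int,
        rounds_left: int,
        update_own_w: bool = True,
        branch: bool = False,
    ) -> BeliefState:
        """Posterior beliefs and irritation weights after one completed round.

        Bayesian updating of the partner's guilt/irritability is skipped for
        investments of 0 (the trustee cannot act) and 5 (returning nothing
        already achieves the fair split, so the return is uninformative);
        irritation weights advance regardless.
        """
        key = ("ai", params, beliefs.sig(), a_idx, f_idx, rounds_left, update_own_w, branch)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        p_alpha = beliefs.partner_alpha_belief
        p_zeta = beliefs.partner_zeta_belief
        amt = _AMT[a_idx, f_idx]
        amounts = _AMT[a_idx]

        do_bayes = INVESTOR_BINS[a_idx] not in (0, 5)
        if branch and not self.config.branch_beliefs:
            do_bayes = False
        if do_bayes:
            bank = self._trustee_policy_bank(params, beliefs, a_idx, rounds_left)
            # likelihood of the observed amount (sums aliased fractions)
            like = bank[:, :, amounts == amt].sum(axis=2)
            joint = np.outer(p_alpha, p_zeta) * like
            total = joint.sum()
            if total > 1e-300:
                joint /= total
                p_alpha = tuple(joint.sum(axis=1))
                p_zeta = tuple(joint.sum(axis=0))
            else:
                self.degenerate_evidence = True

        # partner irritation per candidate zeta: triggered by the *investor's*
        # action relative to the modelled trustee's expectation of investments
        exp_inv = self._trustee_expected_investment(params, beliefs, rounds_left)
        w_new = []
        for j, zeta_t in enumerate(ZETA_GRID):
            wj = beliefs.partner_irritation_weights[j]
            ev = irritation_event(INVESTOR_BINS[a_idx], exp_inv, wj, self.config)
            w_new.append(update_irritation(wj, zeta_t, ev))

        w_own = beliefs.own_irritation_weight
        if update_own_w:
            pr = self.predictive_return_dist(params, beliefs, a_idx, rounds_left)
            exp_ret = float(pr @ amounts)
            ev = irritation_event(amt, exp_ret, w_own, self.config)
            w_own = update_irritation(w_own, params.zeta, ev)

        partner = beliefs.partner
        if partner is not None and params.k >= 2:
            # at k == 1 the modelled trustee is level 0 and state-free, so its
            # epistemic state can stay at the prior without changing anything
            partner = self.advance_trustee(
                partner_params(params, 0.0, 0.0),  # alpha/zeta unused by the update
                partner,
                a_idx,
                f_idx,
                rounds_left,
                update_own_w=False,
                branch=branch,
            )
        out = BeliefState(tuple(p_alpha), tuple(p_zeta), tuple(w_new), w_own, partner)
        self._cache[key] = out
        return out

    def _trustee_expected_investment(
        self, params: AgentParams, beliefs: BeliefState, rounds_left: int
    ) -> float:
        """What the modelled trustee expects the investor to invest."""
        if params.k - 1 < 0:
            # the level -1 trustee model holds no investor model: fall back to
            # the uniform mean over the investment bins
            return float(_INVEST.mean())
        pv = self.predictive_invest_dist(
            partner_params(params, 0.0, 0.0), beliefs.partner, rounds_left
        )
        return float(pv @ _INVEST)

    # -- trustee side ------------------------------------------------------

    def trustee_policy(
        self,
        params: AgentParams,
        beliefs: Optional[BeliefState],
        a_idx: int,
        rounds_left: int,
        w: float,
    ) -> np.ndarray:
        """Effective policy over the five return fractions given investment."""
        state_free = beliefs is None or params.k < 0 or _trustee_state_free(params)
        sig = None if state_free else beliefs.sig()
        key = ("tp", params, sig, a_idx, rounds_left, w)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if params.k < 0:
            normal = _softmax(params.beta * self._u_tr(params.alpha)[a_idx])
        else:
            q = self.trustee_q(
                params, beliefs, a_idx, min(params.planning, rounds_left), rounds_left, w
            )
            normal = _softmax(params.beta * q)
        if w == 0.0:
            pol = normal
        else:
            pol = (1.0 - w) * normal + w * self._irr_trustee_policy(params, a_idx)
        pol.setflags(write=False)
        self._cache[key] = pol
        return pol

    def trustee_q(
        self,
        params: AgentParams,
        beliefs: Optional[BeliefState],
        a_idx: int,
        horizon: int,
        rounds_left: int,
        w: float,
    ) -> np.ndarray:
        """Expectimax return values for a level>=0 trustee."""
        horizon = min(horizon, rounds_left)
        state_free = beliefs is None or _trustee_state_free(params)
        sig = None if state_free else beliefs.sig()
        key = ("tq", params, sig, a_idx, horizon, rounds_left, w)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        q = self._u_tr(params.alpha)[a_idx].astype(float).copy()
        if horizon > 1 and rounds_left > 1:
            exp_inv = self._own_expected_investment(params, beliefs, rounds_left)
            ev = irritation_event(INVESTOR_BINS[a_idx], exp_inv, w, self.config)
            w2 = update_irritation(w, params.zeta, ev)
            for f_idx in range(5):
                nxt = beliefs if state_free else self.advance_trustee(
                    params, beliefs, a_idx, f_idx, rounds_left,
                    update_own_w=False, branch=True,
                )
                pv = self.predictive_invest_dist(params, nxt, rounds_left - 1)
                v = 0.0
                for a2 in range(N_ACTIONS):
                    if pv[a2] <= 1e-14:
                        continue
                    v += pv[a2] * self._trustee_value_given(
                        params, nxt, a2, horizon - 1, rounds_left - 1, w2
                    )
                q[f_idx] += v
        q.setflags(write=False)
        self._cache[key] = q
        return q

    def _trustee_value_given(
        self,
        params: AgentParams,
        beliefs: Optional[BeliefState],
        a_idx: int,
        horizon: int,
        rounds_left: int,
        w: float,
    ) -> float:
        state_free = beliefs is None or _trustee_state_free(params)
        sig = None if state_free else beliefs.sig()
        key = ("tv", params, sig, a_idx, horizon, rounds_left, w)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        q = self.trustee_q(params, beliefs, a_idx, horizon, rounds_left, w)
        normal = _softmax(params.beta * q)
        if w > 0.0:
            pol = (1.0 - w) * normal + w * self._irr_trustee_policy(params, a_idx)
        else:
            pol = normal
        val = float(pol @ q)
        self._cache[key] = val
        return val

    def _own_expected_investment(
        self, params: AgentParams, beliefs: Optional[BeliefState], rounds_left: int
    ) -> float:
        if beliefs is None:
            return float(_INVEST.mean())
        pv = self.predictive_invest_dist(params, beliefs, rounds_left)
        return float(pv @ _INVEST)

    def predictive_invest_dist(
        self, params: AgentParams, beliefs: BeliefState, rounds_left: int
    ) -> np.ndarray:
        """The trustee's marginal prediction of the next investment."""
        sig = None if _trustee_state_free(params) else beliefs.sig()
        key = ("pid", params, sig, rounds_left)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        inv_level = params.k - 1
        if inv_level < 0:
            acc = self._irr_investor_policy(params).copy()
        else:
            acc = np.zeros(N_ACTIONS)
            for i, alpha_i in enumerate(ALPHA_GRID):
                if beliefs.partner_alpha_belief[i] <= 1e-14:
                    continue
                for j, zeta_i in enumerate(ZETA_GRID):
                    pw = beliefs.partner_alpha_belief[i] * beliefs.partner_zeta_belief[j]
                    if pw <= 1e-14:
                        continue
                    pol = self.investor_policy(
                        partner_params(params, alpha_i, zeta_i),
                        beliefs.partner,
                        rounds_left,
                        beliefs.partner_irritation_weights[j],
                    )
                    acc += pw * pol
            acc = acc / acc.sum()
        acc.setflags(write=False)
        self._cache[key] = acc
        return acc

    def advance_trustee(
        self,
        params: AgentParams,
        beliefs: BeliefState,
        a_idx: int,
        f_idx: int,
        rounds_left: int,
        update_own_w: bool = True,
        branch: bool = False,
    ) -> BeliefState:
        """The trustee's end-of-round update from the observed exchange.

        Every investment is informative for the trustee, so there is no
        skip rule on this side.
        """
        key = ("at", params, beliefs.sig(), a_idx, f_idx, rounds_left, update_own_w, branch)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        p_alpha = beliefs.partner_alpha_belief
        p_zeta = beliefs.partner_zeta_belief
        inv_level = params.k - 1

        do_bayes = not (branch and not self.config.branch_beliefs)
        if do_bayes:
            like = np.zeros((len(ALPHA_GRID), len(ZETA_GRID)))
            for i, alpha_i in enumerate(ALPHA_GRID):
                for j, zeta_i in enumerate(ZETA_GRID):
                    pol = self.investor_policy(
                        partner_params(params, alpha_i, zeta_i),
                        beliefs.partner,
                        rounds_left,
                        beliefs.partner_irritation_weights[j],
                    )
                    like[i, j] = float(pol[a_idx])
            joint = np.outer(p_alpha, p_zeta) * like
            total = joint.sum()
            if total > 1e-300:
                joint /= total
                p_alpha = tuple(joint.sum(axis=1))
                p_zeta = tuple(joint.sum(axis=0))
            else:
                self.degenerate_evidence = True

        # modelled investor irritation: triggered by the return falling short
        # of the modelled investor's expectation
        amt = float(_AMT[a_idx, f_idx])
        if inv_level < 0:
            exp_ret = float(_AMT[a_idx].mean())  # no model: uniform over the grid
        else:
            pr = self.predictive_return_dist(
                partner_params(params, 0.0, 0.0), beliefs.partner, a_idx, rounds_left
            )
            exp_ret = float(pr @ _AMT[a_idx])
        w_new = []
        for j, zeta_i in enumerate(ZETA_GRID):
            wj = beliefs.partner_irritation_weights[j]
            ev = irritation_event(amt, exp_ret, wj, self.config)
            w_new.append(update_irritation(wj, zeta_i, ev))

        w_own = beliefs.own_irritation_weight
        if update_own_w:
            exp_inv = self._own_expected_investment(params, beliefs, rounds_left)
            ev = irritation_event(INVESTOR_BINS[a_idx], exp_inv, w_own, self.config)
            w_own = update_irritation(w_own, params.zeta, ev)

        partner = beliefs.partner
        if partner is not None:
            partner = self.advance_investor(
                partner_params(params, 0.0, 0.0),
                partner,
                a_idx,
                f_idx,
                rounds_left,
                update_own_w=False,
                branch=branch,
            )
        out = BeliefState(tuple(p_alpha), tuple(p_zeta), tuple(w_new), w_own, partner)
        self._cache[key] = out
        return out

    # -- public, role-dispatching conveniences ------------------------------

    def effective_policy(
        self,
        params: AgentParams,
        beliefs: BeliefState,
        rounds_left: int,
        a_idx: Optional[int] = None,
    ) -> np.ndarray:
        """Mixture policy (1-w) * normal + w * irritated for either role."""
        if params.role == "investor":
            return self.investor_policy(
                params, beliefs, rounds_left, beliefs.own_irritation_weight
            )
        if a_idx is None:
            raise ValueError("trustee policy requires the pending investment bin index")
        return self.trustee_policy(
            params, beliefs, a_idx, rounds_left, beliefs.own_irritation_weight
        )

    def advance(
        self,
        params: AgentParams,
        beliefs: BeliefState,
        a_idx: int,
        f_idx: int,
        rounds_left: int,
    ) -> BeliefState:
        """End-of-round update for a top-level agent of either role."""
        if params.role == "investor":
            return self.advance_investor(
                params, beliefs, a_idx, f_idx, rounds_left, update_own_w=True
            )
        return self.advance_trustee(
            params, beliefs, a_idx, f_idx, rounds_left, update_own_w=True
        )
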