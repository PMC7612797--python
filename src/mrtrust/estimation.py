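"""Grid-search maximum-likelihood classification and parameter recovery.

Each subject (an investor) is classified by the parameter vector that
minimises the negative log-likelihood of their ten observed investments,
with beliefs and irritation advanced along the observed history between
rounds.  The search is exhaustive over a (restriction of the) seven-way
parameter product grid; ties break on a fixed lexicographic parameter order.

``fit_subject`` evaluates every grid point through the general engine.  For
grids confined to myopic non-mentalizing-partner play (k = 0, P = 1) a
vectorised path evaluates the whole (alpha, omega, zeta, q, beta) product at
once; it is checked against the general path in the test-suite and used for
cohort-scale fits.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .agent import (
    AgentParams,
    BETA_GRID,
    DEFAULT_CONFIG,
    Engine,
    K_GRID,
    ModelConfig,
    P_GRID,
    Q_GRID,
    ZETA_GRID,
    _softmax,
    initial_beliefs,
    irritation_prior,
)
from .game import (
    History,
    INVESTOR_BINS,
    return_amounts,
    return_fraction_index,
)
from .preferences import ALPHA_GRID, OMEGA_GRID, _investor_utility_raw, _trustee_utility_raw

LOG_FLOOR = 1e-10

_BIN_INDEX = {b: i for i, b in enumerate(INVESTOR_BINS)}
_AMT = np.array([return_amounts(a) for a in INVESTOR_BINS], dtype=float)
_INVEST = np.array(INVESTOR_BINS, dtype=float)


@dataclass(frozen=True)
class ParameterGrid:
    """A (sub)set of the 3 x 8 x 5 x 4 x 5 x 5 x 4 parameter product."""

    alpha: tuple = ALPHA_GRID
    omega: tuple = OMEGA_GRID
    k: tuple = K_GRID
    planning: tuple = P_GRID
    zeta: tuple = ZETA_GRID
    q: tuple = Q_GRID
    beta: tuple = BETA_GRID

    def points(self):
        """Grid points in the lexicographic tie-break order
        (alpha, omega, k, P, zeta, q, beta ascending)."""
        for a, o, k, p, z, q, b in itertools.product(
            sorted(self.alpha), sorted(self.omega), sorted(self.k),
            sorted(self.planning), sorted(self.zeta), sorted(self.q), sorted(self.beta),
        ):
            yield AgentParams(a, o, k, p, z, q, b, role="investor")

    def size(self) -> int:
        return (
            len(self.alpha) * len(self.omega) * len(self.k) * len(self.planning)
            * len(self.zeta) * len(self.q) * len(self.beta)
        )

    def is_myopic(self) -> bool:
        return tuple(self.k) == (0,) and tuple(self.planning) == (1,)


@dataclass
class FitResult:
    best_params: AgentParams
    nll: float
    per_choice_likelihood: float
    grid_size: int
    ties: int
    floored: bool = False
    nll_by_point: Optional[np.ndarray] = None


def history_indices(trajectory: History) -> list[tuple[int, int]]:
    """(investment bin index, return fraction index) per round."""
    out = []
    for rec in trajectory:
        out.append((_BIN_INDEX[rec.a_i], return_fraction_index(rec.a_i, rec.a_t)))
    return out


def trajectory_choice_probs(
    trajectory: History,
    params: AgentParams,
    engine: Optional[Engine] = None,
    config: ModelConfig = DEFAULT_CONFIG,
) -> np.ndarray:
    """Model probability of each observed investment, beliefs advanced on the
    observed history between rounds."""
    eng = engine if engine is not None else Engine(config)
    beliefs = initial_beliefs(params, eng.config)
    idx = history_indices(trajectory)
    n = len(idx)
    probs = np.empty(n)
    for t, (a_idx, f_idx) in enumerate(idx):
        r = n - t
        pol = eng.investor_policy(params, beliefs, r, beliefs.own_irritation_weight)
        probs[t] = pol[a_idx]
        beliefs = eng.advance_investor(params, beliefs, a_idx, f_idx, r)
    return probs


def trajectory_nll(
    trajectory: History,
    params: AgentParams,
    engine: Optional[Engine] = None,
    config: ModelConfig = DEFAULT_CONFIG,
    floor: float = LOG_FLOOR,
) -> float:
    """Negative log-likelihood (nats) of the observed investments.

    Probabilities below ``floor`` contribute -log(floor) — the softmax makes
    exact zeros impossible, so the floor only guards numerical underflow.
    """
    probs = trajectory_choice_probs(trajectory, params, engine, config)
    return float(-np.log(np.maximum(probs, floor)).sum())


def per_choice_likelihood(nll: float, n_choices: int) -> float:
    """Geometric-mean per-choice likelihood, exp(-nll / n)."""
    return float(np.exp(-nll / n_choices))


def fit_subject(
    trajectory: History,
    grid: ParameterGrid,
    engine: Optional[Engine] = None,
    config: ModelConfig = DEFAULT_CONFIG,
    keep_nll: bool = False,
) -> FitResult:
    """Exhaustive grid MLE for one trajectory."""
    if grid.size() == 0:
        raise ValueError("empty parameter grid")
    if grid.is_myopic():
        nlls = _nll_myopic_grid(trajectory, grid, config)
    else:
        eng = engine if engine is not None else Engine(config)
        nlls = np.empty(grid.size())
        for i, params in enumerate(grid.points()):
            nlls[i] = trajectory_nll(trajectory, params, eng)
    best_idx = int(np.argmin(nlls))
    best_nll = float(nlls[best_idx])
    ties = int(np.sum(nlls <= best_nll + 1e-9))
    first = next(i for i in range(len(nlls)) if nlls[i] <= best_nll + 1e-9)
    best_params = next(itertools.islice(grid.points(), first, None))
    n = len(trajectory)
    # one floored round alone contributes -log(LOG_FLOOR) ~ 23 nats
    floored = best_nll >= -np.log(LOG_FLOOR)
    return FitResult(
        best_params=best_params,
        nll=float(nlls[first]),
        per_choice_likelihood=per_choice_likelihood(float(nlls[first]), n),
        grid_size=grid.size(),
        ties=ties,
        floored=floored,
        nll_by_point=nlls if keep_nll else None,
    )


# --------------------------------------------------------------------------
# Vectorised myopic-grid path (k = 0, P = 1)


def _nll_myopic_grid(
    trajectory: History, grid: ParameterGrid, config: ModelConfig
) -> np.ndarray:
    """NLL over the full (alpha, omega, zeta, q, beta) product for k=0, P=1.

    Beliefs about the trustee depend only on (beta, q) and the history, so a
    single belief replay per (beta, q) serves every (alpha, omega, zeta).
    """
    idx = history_indices(trajectory)
    n = len(idx)
    alphas = sorted(grid.alpha)
    omegas = sorted(grid.omega)
    zetas = sorted(grid.zeta)
    qs = sorted(grid.q)
    betas = sorted(grid.beta)
    na, no, nz = len(alphas), len(omegas), len(zetas)

    zeta_full = np.array(ZETA_GRID)
    # utility tables
    u_inv = np.array(
        [
            [
                [
                    [_investor_utility_raw(a, int(_AMT[ai, f]), al, om) for f in range(5)]
                    for ai, a in enumerate(INVESTOR_BINS)
                ]
                for om in omegas
            ]
            for al in alphas
        ]
    )  # (na, no, 5, 5)
    u_tr = np.array(
        [
            [
                [_trustee_utility_raw(a, int(_AMT[ai, f]), al) for f in range(5)]
                for ai, a in enumerate(INVESTOR_BINS)
            ]
            for al in ALPHA_GRID
        ]
    )  # (3 alpha_T, 5, 5)

    nll = np.empty((na, no, nz, len(qs), len(betas)))
    for bi, beta in enumerate(betas):
        # level -1 trustee model per candidate, and its guilt-free variant
        nt = np.empty((5, 3, 5))
        for ai in range(5):
            for ci in range(3):
                nt[ai, ci] = _softmax(beta * u_tr[ci, ai])
        irr_t = np.stack([_softmax(beta * u_tr[0, ai]) for ai in range(5)])  # (5, 5)
        if config.level_neg1_investor == "zero-return":
            irr_i = np.stack(
                [_softmax(beta * om * (20.0 - _INVEST)) for om in omegas]
            )  # (no, 5)
        else:
            irr_i = np.stack([_softmax(beta * u_inv[0, oi].mean(axis=1)) for oi in range(no)])
        for qi, q in enumerate(qs):
            p_alpha = np.full(3, 1 / 3)
            p_zeta = np.array(irritation_prior(q, config))
            w_part = np.zeros(5)
            margs = np.empty((n, 5, 5))
            esc_own = np.empty(n, dtype=bool)
            for t, (a_idx, f_idx) in enumerate(idx):
                mix = (1 - w_part)[None, None, :, None] * nt[:, :, None, :] + w_part[
                    None, None, :, None
                ] * irr_t[:, None, None, :]  # (a, alpha_T, zeta_T, f)
                marg = np.einsum("i,j,aijf->af", p_alpha, p_zeta, mix)
                marg /= marg.sum(axis=1, keepdims=True)
                margs[t] = marg
                amt = _AMT[a_idx, f_idx]
                exp_ret = float(marg[a_idx] @ _AMT[a_idx])
                esc_own[t] = amt < exp_ret - 1e-9
                if INVESTOR_BINS[a_idx] not in (0, 5):
                    like = mix[a_idx, :, :, f_idx]
                    joint = np.outer(p_alpha, p_zeta) * like
                    total = joint.sum()
                    if total > 1e-300:
                        joint /= total
                        p_alpha = joint.sum(axis=1)
                        p_zeta = joint.sum(axis=0)
                # modelled trustee irritation: uniform-mean expectation (10)
                if INVESTOR_BINS[a_idx] < _INVEST.mean() - 1e-9:
                    w_part = np.minimum(1.0, w_part + zeta_full)
                else:
                    w_part = np.maximum(0.0, w_part - zeta_full)

            # own irritation trajectories per own zeta (policy uses pre-round w)
            w_own = np.zeros((n, nz))
            w = np.zeros(nz)
            zs = np.array(zetas)
            for t in range(n):
                w_own[t] = w
                w = np.where(esc_own[t], np.minimum(1.0, w + zs), np.maximum(0.0, w - zs))

            q_vals = np.einsum("taf,xyaf->txya", margs, u_inv)  # (t, na, no, 5)
            z = beta * q_vals
            z -= z.max(axis=-1, keepdims=True)
            ez = np.exp(z)
            normal = ez / ez.sum(axis=-1, keepdims=True)
            obs = np.array([a for a, _ in idx])
            eff = (
                (1.0 - w_own)[:, None, None, :, None] * normal[:, :, :, None, :]
                + w_own[:, None, None, :, None] * irr_i[None, None, :, None, :]
            )  # (t, na, no, nz, 5)
            p_obs = eff[np.arange(n), :, :, :, obs]  # (t, na, no, nz)
            nll[:, :, :, qi, bi] = -np.log(np.maximum(p_obs, LOG_FLOOR)).sum(axis=0)

    # flatten in lexicographic (alpha, omega, k, P, zeta, q, beta) order;
    # k and P are singletons here
    return nll.reshape(-1)


# --------------------------------------------------------------------------
# Canonical analysis grids
#
# On ten-round myopic trajectories guilt, irritability and awareness act as
# behavioural mimics of risk aversion (guilt labels ceiling play; a
# pessimistic irritability prior mimics high risk aversion on runs of zero
# investment), so the exhaustive product grid is deliberately cut down per
# analysis: the variance decomposition classifies on the identifiable
# risk-aversion/temperature plane, the demographic regressions add guilt
# because it is an outcome there, and the recovery study frees theory of
# mind and planning as the confusable structural axes.

#: omega x beta — variance decomposition of total investment
DECOMPOSITION_GRID = ParameterGrid(
    alpha=(0.0,), k=(0,), planning=(1,), zeta=(0.0,), q=(0,)
)
#: alpha x omega x beta — demographic regressions (guilt is an outcome)
DEMOGRAPHIC_GRID = ParameterGrid(k=(0,), planning=(1,), zeta=(0.0,), q=(0,))
#: omega x beta x k<=1 x P<=2 — parameter-recovery confusion analysis
RECOVERY_GRID = ParameterGrid(alpha=(0.0,), k=(0, 1), planning=(1, 2),
                              zeta=(0.0,), q=(0,))


def generate_recovery_study(
    n: int,
    seed,
    grid: ParameterGrid = RECOVERY_GRID,
    config: ModelConfig = DEFAULT_CONFIG,
):
    """Stage one of the confusion analysis: simulate ``n`` dyads from
    parameters drawn uniformly on the restricted family (stochastic-play
    temperatures), then classify each on ``grid``.

    The returned records carry ``fitted_params``; the confusion matrix itself
    is obtained by regenerating from those fits (`recovery_confusion` with
    ``use='fitted'``), mirroring a re-estimation from classified subjects.
    """
    from .cohort import CohortConfig, SubjectRecord, draw_trustee, simulate_dyad

    rng = np.random.default_rng(seed)
    cohort_cfg = CohortConfig()
    betas = (0.25, 1 / 3, 0.5)
    engine = Engine(config)
    records = []
    for i in range(n):
        gen = AgentParams(
            alpha=float(rng.choice(sorted(grid.alpha))),
            omega=float(rng.choice(sorted(grid.omega))),
            k=int(rng.choice(sorted(grid.k))),
            planning=int(rng.choice(sorted(grid.planning))),
            zeta=float(rng.choice(sorted(grid.zeta))),
            q=int(rng.choice(sorted(grid.q))),
            beta=float(rng.choice(betas)),
            role="investor",
        )
        trustee = draw_trustee(cohort_cfg, rng)
        engine.clear()
        hist = simulate_dyad(gen, trustee, int(rng.integers(0, 2**31 - 1)),
                             engine=engine)
        engine.clear()
        res = fit_subject(hist, grid, engine=engine, config=config)
        records.append(
            SubjectRecord(
                subject_id=f"R{i:03d}", age=0.0, sex=0, iq=0.0, ses=0.0,
                trajectory=hist, true_params=gen, trustee_params=trustee,
                fitted_params=res.best_params,
            )
        )
    return records


# --------------------------------------------------------------------------
# Cohort fitting and recovery


def fit_cohort(records, grid: ParameterGrid, config: ModelConfig = DEFAULT_CONFIG):
    """Fit every record on the grid, storing ``fitted_params``; returns the
    list of FitResults in record order."""
    engine = Engine(config)
    results = []
    for rec in records:
        engine.clear()
        res = fit_subject(rec.trajectory, grid, engine=engine, config=config)
        rec.fitted_params = res.best_params
        results.append(res)
    return results


@dataclass
class RecoveryMatrix:
    param_name: str
    values: tuple
    matrix: np.ndarray  # rows: generating value, cols: re-estimated value
    counts: np.ndarray

    def row_sums(self) -> np.ndarray:
        return self.matrix.sum(axis=1)

    def within_one_step(self) -> float:
        """Fraction of dyads whose re-estimate lies within one grid step."""
        total = self.counts.sum()
        ok = sum(
            self.counts[i, j]
            for i in range(self.counts.shape[0])
            for j in range(self.counts.shape[1])
            if abs(i - j) <= 1
        )
        return ok / total if total else float("nan")

    def adjacent_misestimate_share(self) -> float:
        """Among misestimations, the share landing on an adjacent grid value."""
        off = sum(
            self.counts[i, j]
            for i in range(self.counts.shape[0])
            for j in range(self.counts.shape[1])
            if i != j
        )
        adj = sum(
            self.counts[i, j]
            for i in range(self.counts.shape[0])
            for j in range(self.counts.shape[1])
            if abs(i - j) == 1
        )
        return adj / off if off else 1.0


def recovery_confusion(
    param_name: str,
    records,
    grid: ParameterGrid,
    seed,
    config: ModelConfig = DEFAULT_CONFIG,
    use: str = "true",
) -> RecoveryMatrix:
    """Simulate one fresh dyad per subject from its (true or fitted)
    parameters, refit, and tabulate conditional re-estimation frequencies."""
    from .cohort import simulate_dyad  # deferred: cohort imports estimation users

    rng = np.random.default_rng(seed)
    values = tuple(sorted(getattr(grid, param_name if param_name != "P" else "planning")))
    vindex = {v: i for i, v in enumerate(values)}
    counts = np.zeros((len(values), len(values)))
    engine = Engine(config)
    attr = param_name if param_name != "P" else "planning"
    for rec in records:
        gen = rec.true_params if use == "true" else rec.fitted_params
        if gen is None:
            raise ValueError(f"record {rec.subject_id} lacks {use} parameters")
        engine.clear()
        hist = simulate_dyad(
            gen, rec.trustee_params, rng.integers(0, 2**31 - 1), config, engine=engine
        )
        engine.clear()
        res = fit_subject(hist, grid, engine=engine, config=config)
        counts[vindex[getattr(gen, attr)], vindex[getattr(res.best_params, attr)]] += 1
    with np.errstate(invalid="ignore"):
        matrix = counts / counts.sum(axis=1, keepdims=True)
    matrix = np.nan_to_num(matrix)
    # rows with no mass are reported as all-zero rather than ill-defined
    return RecoveryMatrix(param_name=param_name, values=values, matrix=matrix, counts=counts)
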