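"""Statistical analyses over fitted cohorts.

Covers the variance decomposition of total investment on the seven fitted
parameters, linear/quadratic and proportional-odds demographic regressions
with backward stepwise AIC selection, Kendall tau-b correlation tables, Welch
group comparisons with Cohen's d, and zero-investment summaries.

Ordinary model fits go through statsmodels (OLS, logit OrderedModel); the
selection loop, table conventions and derived effect sizes are local.
Slope signs from the ordinal fits follow the proportional-odds convention in
which a positive coefficient shifts mass toward higher outcome categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.miscmodels.ordinal_model import OrderedModel


@dataclass
class RegressionResult:
    outcome: str
    kind: str  # "ols" | "ordinal"
    terms: tuple[str, ...]
    coefficients: dict[str, float]
    std_errors: dict[str, float]
    p_values: dict[str, float]
    aic: float
    n: int
    adj_r2: Optional[float] = None
    thresholds: tuple[float, ...] = ()
    dropped_terms: tuple[str, ...] = ()
    converged: bool = True


@dataclass
class CorrelationTable:
    variables: tuple[str, ...]
    tau: pd.DataFrame
    p: pd.DataFrame


def zscore(values: Sequence[float]) -> np.ndarray:
    """Standardize to mean 0, sample sd 1 (squared terms are built *after*
    z-scoring)."""
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("cannot z-score a constant input")
    return (x - x.mean()) / sd


def _design(data: pd.DataFrame, terms: Sequence[str]) -> tuple[pd.DataFrame, tuple[str, ...]]:
    """Design matrix for the requested terms, dropping rank-deficient columns
    (constant or collinear) with a warning."""
    X = data.loc[:, list(terms)].astype(float).copy()
    kept: list[str] = []
    dropped: list[str] = []
    for term in terms:
        candidate = X[kept + [term]].to_numpy()
        cand_aug = np.column_stack([np.ones(len(X)), candidate])
        if np.linalg.matrix_rank(cand_aug) == len(kept) + 2:
            kept.append(term)
        else:
            dropped.append(term)
    if dropped:
        warnings.warn(f"dropping rank-deficient terms: {dropped}", stacklevel=2)
    return X[kept], tuple(dropped)


def ols_fit(data: pd.DataFrame, outcome: str, terms: Sequence[str]) -> RegressionResult:
    """Least-squares fit of ``outcome ~ 1 + terms``; fitted model parameters
    enter as ordinal numeric values."""
    y = data[outcome].astype(float)
    X, dropped = _design(data, terms)
    if len(y) <= len(X.columns) + 1:
        raise ValueError("need n greater than the number of terms")
    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    names = ["const"] + list(X.columns)
    return RegressionResult(
        outcome=outcome,
        kind="ols",
        terms=tuple(X.columns),
        coefficients={t: float(model.params[t]) for t in names},
        std_errors={t: float(model.bse[t]) for t in names},
        p_values={t: float(model.pvalues[t]) for t in names},
        aic=float(model.aic),
        n=int(model.nobs),
        adj_r2=float(model.rsquared_adj),
        dropped_terms=dropped,
    )


def ordinal_fit(data: pd.DataFrame, outcome: str, terms: Sequence[str]) -> RegressionResult:
    """Proportional-odds (cumulative logit) fit of an ordinal outcome.

    Ordered intercepts are reported without p-values; empty top levels are
    dropped before fitting so every threshold is identifiable.  Complete
    separation surfaces as a non-convergence diagnostic, not a crash.
    """
    y = pd.Categorical(data[outcome], ordered=True)
    y = y.remove_unused_categories()
    if len(y.categories) < 2:
        raise ValueError("ordinal outcome needs at least two observed levels")
    X, dropped = _design(data, terms)
    mod = OrderedModel(y, X if len(X.columns) else None, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = mod.fit(method="bfgs", maxiter=500, disp=False)
    converged = bool(res.mle_retvals.get("converged", True))
    k_thresh = len(y.categories) - 1
    slopes = list(X.columns)
    coefs = {t: float(res.params[t]) for t in slopes}
    ses = {t: float(res.bse[t]) for t in slopes}
    pvals = {t: float(res.pvalues[t]) for t in slopes}
    thresholds = tuple(float(v) for v in np.asarray(res.params)[len(slopes):][:k_thresh])
    return RegressionResult(
        outcome=outcome,
        kind="ordinal",
        terms=tuple(slopes),
        coefficients=coefs,
        std_errors=ses,
        p_values=pvals,
        aic=float(res.aic),
        n=int(res.nobs),
        thresholds=thresholds,
        dropped_terms=dropped,
        converged=converged,
    )


def stepwise_aic(
    data: pd.DataFrame,
    outcome: str,
    terms: Sequence[str],
    fitter: Callable[[pd.DataFrame, str, Sequence[str]], RegressionResult] = ols_fit,
) -> RegressionResult:
    """Backward elimination on AIC: at each step drop the single term whose
    removal improves AIC most; stop when no deletion improves it."""
    current = list(terms)
    best = fitter(data, outcome, current)
    while current:
        candidates = []
        for term in current:
            reduced = [t for t in current if t != term]
            try:
                candidates.append((fitter(data, outcome, reduced).aic, term))
            except (ValueError, np.linalg.LinAlgError):
                continue
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1]))
        best_aic, drop = candidates[0]
        if best_aic < best.aic - 1e-9:
            current.remove(drop)
            best = fitter(data, outcome, current)
        else:
            break
    return best


def kendall_matrix(data: pd.DataFrame, variables: Sequence[str]) -> CorrelationTable:
    """Tie-adjusted Kendall tau-b with asymptotic p-values; diagonal tau = 1
    and diagonal p = 0, matching the below-diagonal reporting convention."""
    vs = tuple(variables)
    tau = pd.DataFrame(np.eye(len(vs)), index=vs, columns=vs)
    p = pd.DataFrame(np.zeros((len(vs), len(vs))), index=vs, columns=vs)
    for i, a in enumerate(vs):
        for j in range(i):
            b = vs[j]
            x, y = data[a].to_numpy(float), data[b].to_numpy(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                t_val, p_val = np.nan, np.nan
            else:
                t_val, p_val = sps.kendalltau(x, y)
            tau.loc[a, b] = tau.loc[b, a] = t_val
            p.loc[a, b] = p.loc[b, a] = p_val
    return CorrelationTable(variables=vs, tau=tau, p=p)


@dataclass
class GroupComparison:
    mean_difference: float
    ci_low: float
    ci_high: float
    welch_t: float
    welch_p: float
    cohens_d: float
    group_means: dict
    group_sds: dict
    group_ns: dict


def group_compare(values: Sequence[float], groups: Sequence) -> GroupComparison:
    """Welch two-sample comparison with 95% CI for the mean difference and
    Cohen's d on the pooled standard deviation."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    labels = sorted(pd.unique(g).tolist())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    x0, x1 = v[g == labels[0]], v[g == labels[1]]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError("each group needs n >= 2")
    t_stat, p_val = sps.ttest_ind(x0, x1, equal_var=False)
    n0, n1 = len(x0), len(x1)
    v0, v1 = x0.var(ddof=1), x1.var(ddof=1)
    se = np.sqrt(v0 / n0 + v1 / n1)
    df = (v0 / n0 + v1 / n1) ** 2 / ((v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1))
    delta = x0.mean() - x1.mean()
    half = sps.t.ppf(0.975, df) * se
    pooled = np.sqrt(((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2))
    d = delta / pooled if pooled > 0 else 0.0
    return GroupComparison(
        mean_difference=float(delta),
        ci_low=float(delta - half),
        ci_high=float(delta + half),
        welch_t=float(t_stat),
        welch_p=float(p_val),
        cohens_d=float(d),
        group_means={labels[0]: float(x0.mean()), labels[1]: float(x1.mean())},
        group_sds={labels[0]: float(x0.std(ddof=1)), labels[1]: float(x1.std(ddof=1))},
        group_ns={labels[0]: n0, labels[1]: n1},
    )


def zero_investment_summary(records) -> pd.DataFrame:
    """Counts and shares of zero-investment rounds split by sex."""
    counts = {0: 0, 1: 0}
    for rec in records:
        z = sum(1 for rr in rec.trajectory if rr.a_i == 0)
        counts[rec.sex] = counts.get(rec.sex, 0) + z
    total = sum(counts.values())
    rows = []
    for sex, label in ((0, "male"), (1, "female")):
        share = 100.0 * counts.get(sex, 0) / total if total else np.nan
        rows.append({"sex": label, "zero_investments": counts.get(sex, 0), "share_pct": share})
    out = pd.DataFrame(rows).set_index("sex")
    out.attrs["total"] = total
    return out


def zero_investment_shares(count_male: int, count_female: int) -> tuple[float, float]:
    """Percentage split of zero-investment rounds between the sexes."""
    total = count_male + count_female
    if total == 0:
        return float("nan"), float("nan")
    return 100.0 * count_male / total, 100.0 * count_female / total


# --------------------------------------------------------------------------
# Cohort-level assembly


PARAM_COLUMNS = ("alpha", "omega", "k", "planning", "zeta", "q", "beta")
DEMO_TERMS = ("age", "iq", "ses", "sex", "age2", "iq2", "ses2")


def cohort_frame(records, which: str = "fitted") -> pd.DataFrame:
    """Flat table: demographics (z-scored, squared-after-z), parameters and
    investment summaries for a fitted cohort."""
    rows = []
    for rec in records:
        params = rec.fitted_params if which == "fitted" else rec.true_params
        if params is None:
            raise ValueError(f"record {rec.subject_id} has no {which} parameters")
        rows.append(
            {
                "subject_id": rec.subject_id,
                "age_raw": rec.age,
                "sex": rec.sex,
                "iq_raw": rec.iq,
                "ses_raw": rec.ses,
                "total_investment": rec.total_investment,
                "total_earnings": rec.total_earnings,
                **{c: getattr(params, c) for c in PARAM_COLUMNS},
            }
        )
    df = pd.DataFrame(rows)
    for raw, name in (("age_raw", "age"), ("iq_raw", "iq"), ("ses_raw", "ses")):
        df[name] = zscore(df[raw])
        df[name + "2"] = df[name] ** 2
    return df


def variance_decomposition(df: pd.DataFrame) -> dict[str, float]:
    """Adjusted R^2 of total investment on all seven fitted parameters and on
    each parameter alone."""
    out = {"all": ols_fit(df, "total_investment", PARAM_COLUMNS).adj_r2}
    for c in PARAM_COLUMNS:
        if df[c].nunique() < 2:
            out[c] = 0.0
        else:
            out[c] = ols_fit(df, "total_investment", (c,)).adj_r2
    return out
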