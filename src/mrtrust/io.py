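"""Delimited-text readers and writers for trajectories, cohorts and fits.

Everything round-trips: each writer's output is accepted by the matching
reader.  Trajectory files carry raw coin values; the reader applies the
investment/return discretizers and validates against the rules of the game.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .agent import AgentParams
from .cohort import SubjectRecord
from .game import (
    History,
    InvalidTrajectoryError,
    N_ROUNDS,
    discretize_investment,
    discretize_return,
)

TRAJECTORY_COLUMNS = ["subject_id", "round", "investment", "return"]
COHORT_COLUMNS = ["subject_id", "age", "sex", "iq", "ses"]
PARAM_COLUMNS = ["alpha", "omega", "k", "planning", "zeta", "q", "beta"]


def write_trajectories(records: list[SubjectRecord], path) -> None:
    rows = []
    for rec in records:
        for rr in rec.trajectory:
            rows.append((rec.subject_id, rr.round_index, rr.a_i, rr.a_t))
    pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS).to_csv(path, index=False)


def read_trajectories(path) -> dict[str, History]:
    """Parse, discretize and validate a trajectory table."""
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidTrajectoryError(f"{path}: missing columns {sorted(missing)}")
    df = df.rename(columns={"return": "repayment"})
    out: dict[str, History] = {}
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            a_i = discretize_investment(row.investment)
            a_t = discretize_return(row.repayment, a_i)
        except (InvalidTrajectoryError, TypeError, ValueError) as exc:
            raise InvalidTrajectoryError(f"{path}, line {line_no}: {exc}") from exc
        hist = out.setdefault(str(row.subject_id), History())
        if int(row.round) != len(hist) + 1:
            raise InvalidTrajectoryError(
                f"{path}, line {line_no}: round {row.round} out of order for "
                f"subject {row.subject_id}"
            )
        hist.append(a_i, a_t)
    for sid, hist in out.items():
        hist.validate()
        if len(hist) != N_ROUNDS:
            raise InvalidTrajectoryError(f"subject {sid}: expected {N_ROUNDS} rounds, got {len(hist)}")
    return out


def write_cohort(records: list[SubjectRecord], path) -> None:
    pd.DataFrame(
        [(r.subject_id, r.age, r.sex, r.iq, r.ses) for r in records],
        columns=COHORT_COLUMNS,
    ).to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise InvalidTrajectoryError(f"{path}: missing columns {sorted(missing)}")
    return df


def _params_row(params: AgentParams) -> list:
    return [params.alpha, params.omega, params.k, params.planning, params.zeta,
            params.q, params.beta]


def write_params(records: list[SubjectRecord], path, which: str = "true") -> None:
    rows = []
    for rec in records:
        p = {"true": rec.true_params, "fitted": rec.fitted_params,
             "trustee": rec.trustee_params}[which]
        rows.append([rec.subject_id] + _params_row(p))
    pd.DataFrame(rows, columns=["subject_id"] + PARAM_COLUMNS).to_csv(path, index=False)


def read_params(path, role: str = "investor") -> dict[str, AgentParams]:
    df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        out[str(row.subject_id)] = AgentParams(
            alpha=float(row.alpha), omega=float(row.omega), k=int(row.k),
            planning=int(row.planning), zeta=float(row.zeta), q=int(row.q),
            beta=float(row.beta), role=role,
        ).validate()
    return out


def write_fits(fit_results, subject_ids, path) -> None:
    rows = []
    for sid, res in zip(subject_ids, fit_results):
        rows.append(
            [sid] + _params_row(res.best_params)
            + [res.nll, res.per_choice_likelihood, res.ties]
        )
    pd.DataFrame(
        rows, columns=["subject_id"] + PARAM_COLUMNS + ["nll", "per_choice_likelihood", "ties"]
    ).to_csv(path, index=False)


def write_provenance(path, command: str, seed, config_echo: dict) -> None:
    from . import __version__

    payload = {"command": command, "seed": seed, "version": __version__,
               "config": config_echo}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
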