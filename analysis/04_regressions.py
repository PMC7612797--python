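#!/usr/bin/env python
"""Statistical analyses over the fitted cohort.

Variance decomposition of total investment on the fitted parameters;
backward stepwise-AIC demographic regressions (linear for risk aversion and
temperature, proportional-odds for guilt); Kendall tau-b correlation tables
for demographics and parameters; sex comparison of total earnings; and the
zero-investment summary.  Writes tables under results/analysis/."""

import json
from pathlib import Path

import pandas as pd

from mrtrust import io
from mrtrust.stats import (
    DEMO_TERMS,
    cohort_frame,
    group_compare,
    kendall_matrix,
    ols_fit,
    ordinal_fit,
    stepwise_aic,
    variance_decomposition,
    zero_investment_summary,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def load(which: str):
    import importlib.util

    spec = importlib.util.spec_from_file_location(
        "fit_step", Path(__file__).resolve().parent / "02_fit_cohort.py"
    )
    mod = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(mod)
    records = mod.load_records()
    fits = io.read_params(ROOT / "fits" / f"fits_{which}.csv")
    for rec in records:
        rec.fitted_params = fits[rec.subject_id]
    return records


def fmt(res) -> str:
    head = f"{res.outcome} ({res.kind}): AIC={res.aic:.1f}"
    if res.adj_r2 is not None:
        head += f" adjR2={res.adj_r2:.3f}"
    lines = [head]
    for t in res.terms:
        lines.append(f"  {t:>5s} b={res.coefficients[t]: .4f} p={res.p_values[t]:.3g}")
    if not res.terms:
        lines.append("  (intercept only)")
    return "\n".join(lines)


def main() -> None:
    out = ROOT / "analysis"
    out.mkdir(parents=True, exist_ok=True)

    # variance decomposition on the risk-aversion/temperature classification
    rec_dec = load("decomposition")
    df_dec = cohort_frame(rec_dec, which="fitted")
    dec = variance_decomposition(df_dec)
    pd.Series(dec, name="adj_r2").to_csv(out / "variance_decomposition.csv")
    print("adjusted R^2 of total investment:")
    for k, v in dec.items():
        print(f"  {k:>8s}: {v:.3f}")

    # demographic regressions on the guilt-inclusive classification
    rec_dem = load("demographic")
    df = cohort_frame(rec_dem, which="fitted")
    report = []
    for outcome in ("omega", "beta"):
        report.append(fmt(stepwise_aic(df, outcome, DEMO_TERMS, ols_fit)))
    for outcome in ("alpha",):
        if df[outcome].nunique() >= 2:
            report.append(fmt(stepwise_aic(df, outcome, DEMO_TERMS, ordinal_fit)))
    (out / "regressions.txt").write_text("\n\n".join(report) + "\n")
    print("\nselected demographic models:")
    print("\n\n".join(report))

    demo_tab = kendall_matrix(df, ["age", "iq", "ses", "sex"])
    demo_tab.tau.to_csv(out / "demographics_tau.csv")
    demo_tab.p.to_csv(out / "demographics_p.csv")
    par_tab = kendall_matrix(df, ["k", "planning", "omega", "beta", "alpha",
                                  "zeta", "q"])
    par_tab.tau.to_csv(out / "parameters_tau.csv")
    par_tab.p.to_csv(out / "parameters_p.csv")

    comp = group_compare(df["total_earnings"], df["sex"])
    zi = zero_investment_summary(rec_dem)
    summary = {
        "male_mean_earnings": comp.group_means[0],
        "female_mean_earnings": comp.group_means[1],
        "mean_difference": comp.mean_difference,
        "ci95": [comp.ci_low, comp.ci_high],
        "welch_p": comp.welch_p,
        "cohens_d": comp.cohens_d,
        "zero_investment_counts": zi["zero_investments"].to_dict(),
        "zero_investment_share_pct": zi["share_pct"].round(1).to_dict(),
    }
    (out / "group_summary.json").write_text(json.dumps(summary, indent=2))
    print("\nearnings by sex: male "
          f"{comp.group_means[0]:.0f} vs female {comp.group_means[1]:.0f} "
          f"(d = {comp.cohens_d:.2f}, Welch p = {comp.welch_p:.2g})")
    print(f"zero-investment shares: {summary['zero_investment_share_pct']}")


if __name__ == "__main__":
    main()
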