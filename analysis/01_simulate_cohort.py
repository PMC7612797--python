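#!/usr/bin/env python
"""Simulate the default synthetic cohort (n = 784, ages 14-25, balanced sex)
and write trajectories, demographics, true parameters and ensemble
summaries (per-round investment/repayment curves, earnings quintiles by sex,
investment by risk aversion) under results/cohort/."""

from pathlib import Path

import numpy as np

from mrtrust import io
from mrtrust.cohort import CohortConfig, generate_cohort, summarize_ensemble

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = CohortConfig(n=784, seed=seed)
    records = generate_cohort(cfg)
    io.write_trajectories(records, OUT / "trajectories.csv")
    io.write_cohort(records, OUT / "cohort.csv")
    io.write_params(records, OUT / "params_true.csv", which="true")
    io.write_provenance(OUT / "provenance.json", "01_simulate_cohort", seed,
                        {"n": cfg.n})

    summ = summarize_ensemble(records)
    summ["per_round"].to_csv(OUT / "per_round_means.csv")
    summ["quintiles"].to_csv(OUT / "earnings_quintiles_by_sex.csv")
    summ["by_omega"].to_csv(OUT / "investment_by_omega.csv")

    mean_inv = np.mean([r.total_investment for r in records]) / 10
    zero = np.mean([sum(rr.a_i == 0 for rr in r.trajectory) for r in records]) / 10
    print(f"cohort of {len(records)} subjects written to {OUT}")
    print(f"mean investment per round: {mean_inv:.2f} coins; "
          f"zero-investment rounds: {100 * zero:.1f}%")
    print("mean total investment by true risk aversion:")
    print(summ["by_omega"]["mean"].round(1).to_string())


if __name__ == "__main__":
    main()
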