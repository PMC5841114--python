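#!/usr/bin/env python
"""Prognostic workflow on a simulated cohort.

Simulates a 221-patient cohort whose overall-survival hazard rises
log-linearly with WBTLG (beta = 0.003 per unit, the order of magnitude
implied by a hazard ratio of ~1.002-1.003 per WBTLG unit), then runs
the full prognostic chain: ROC cutoff selection (Youden), Kaplan-Meier
stratification with log-rank, and the seven-covariate multivariate Cox
model for OS and DFS.

Writes results/cohort_simulated.csv, results/prognosis_cutoff.csv,
results/prognosis_km.csv, results/prognosis_cox_os.csv and
results/prognosis_cox_dfs.csv.
"""

from pathlib import Path

import pandas as pd

from petquant.cohort_stats import (
    cox_multivariate,
    km_stratified,
    roc_optimal_cutoff,
)
from petquant.phantom import CohortSimSpec, generate_cohort

RESULTS = Path(__file__).resolve().parents[1] / "results"
SEED = 20260925


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = generate_cohort(CohortSimSpec(n_patients=221, rng_seed=SEED))
    cohort.to_csv(RESULTS / "cohort_simulated.csv", index=False)
    print(f"simulated cohort: {len(cohort)} patients, "
          f"{int(cohort.os_event.sum())} deaths, "
          f"median WBTLG {cohort.wbtlg.median():.1f} "
          f"(mean {cohort.wbtlg.mean():.1f} - right-skewed)")

    cut = roc_optimal_cutoff(cohort.wbtlg, cohort.os_event, biomarker="wbtlg")
    pd.DataFrame([cut.__dict__]).to_csv(RESULTS / "prognosis_cutoff.csv",
                                        index=False)
    print(f"ROC: AUC {cut.auc:.3f}, Youden cutoff {cut.cutoff:.2f} "
          f"(sens {cut.sensitivity:.2f}, spec {cut.specificity:.2f})")

    km = km_stratified(cohort, "wbtlg", cut.cutoff, horizon_months=60)
    pd.DataFrame([{k: v for k, v in km.__dict__.items()
                   if not k.startswith("km_")}]).to_csv(
        RESULTS / "prognosis_km.csv", index=False)
    print(f"5-year OS: {100 * km.survival_low:.1f}% (WBTLG < cutoff, "
          f"n={km.n_low}) vs {100 * km.survival_high:.1f}% (>= cutoff, "
          f"n={km.n_high}); log-rank chi2 {km.logrank_chi2:.1f}, "
          f"p = {km.logrank_p:.2g}")

    for endpoint in ("OS", "DFS"):
        table = cox_multivariate(cohort, endpoint)
        table.to_csv(RESULTS / f"prognosis_cox_{endpoint.lower()}.csv")
        wbtlg = table.loc["wbtlg"]
        print(f"Cox {endpoint}: WBTLG HR {wbtlg['hr']:.4f} "
              f"[{wbtlg['ci_lower']:.4f}, {wbtlg['ci_upper']:.4f}], "
              f"p = {wbtlg['p']:.3g}")


if __name__ == "__main__":
    main()
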