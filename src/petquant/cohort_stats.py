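"""Cohort-level statistics for volumetric PET biomarkers.

Detection-rate comparison across threshold methods (chi-square, with
Fisher's exact test for sparse 2x2 tables), ROC-based cutoff selection
for WBMTV/WBTLG, Kaplan-Meier / log-rank stratified survival, and
multivariate Cox proportional-hazards regression for overall and
disease-free survival.

No multiple-testing correction is applied anywhere; p-values are
reported raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from sklearn.metrics import roc_auc_score

from petquant.segmentation import ThresholdMethod

__all__ = [
    "DetectionTable",
    "CutoffResult",
    "KMResult",
    "detection_rate_table",
    "roc_optimal_cutoff",
    "km_stratified",
    "cox_multivariate",
    "DEFAULT_COX_COVARIATES",
]

#: Covariate set of the default multivariate Cox model.
DEFAULT_COX_COVARIATES = (
    "age", "gender", "treatment", "lesion_count", "suvmax", "wbmtv", "wbtlg",
)

_ENDPOINT_COLUMNS = {
    "OS": ("os_time", "os_event"),
    "DFS": ("dfs_time", "dfs_event"),
}


@dataclass
class DetectionTable:
    """Per-method, per-site detection accounting with significance tests."""

    per_site: pd.DataFrame  # columns: method, site, n_lesions, n_detected
    per_method: pd.DataFrame  # columns: method, n_lesions, n_detected, detection_rate
    global_chi2: float
    global_p: float
    pairwise: pd.DataFrame  # method_a, method_b, test, statistic, p

    def rate(self, method: ThresholdMethod | str) -> float:
        key = method.value if isinstance(method, ThresholdMethod) else method
        row = self.per_method.loc[self.per_method["method"] == key]
        return float(row["detection_rate"].iloc[0])


def detection_rate_table(statuses: pd.DataFrame) -> DetectionTable:
    """Tabulate detection rates per method and compare them.

    Parameters
    ----------
    statuses : DataFrame
        One row per lesion x method with columns ``lesion_id, site,
        method, detected`` (boolean; a lesion is detected iff its
        segmentation status is DETECTED).  Every lesion must carry a
        status for every method.

    Returns
    -------
    DetectionTable
        Per-method rates, the global 4x2 chi-square over detected vs
        not by method, and all pairwise 2x2 comparisons (chi-square,
        switching to Fisher's exact test when any expected cell count
        is below 5).
    """
    required = {"lesion_id", "site", "method", "detected"}
    missing = required - set(statuses.columns)
    if missing:
        raise ValueError(f"statuses missing columns: {sorted(missing)}")

    methods = sorted(statuses["method"].unique())
    counts = statuses.groupby("method")["detected"].agg(["count", "sum"])
    if counts["count"].nunique() != 1:
        raise ValueError("every lesion must have a status for every method")
    per_lesion = statuses.groupby("lesion_id")["method"].nunique()
    if (per_lesion != len(methods)).any():
        bad = per_lesion.index[per_lesion != len(methods)].tolist()
        raise ValueError(f"lesions missing statuses for some methods: {bad[:5]}")

    per_site = (
        statuses.groupby(["method", "site"])["detected"]
        .agg(n_lesions="count", n_detected="sum")
        .reset_index()
    )
    per_method = (
        statuses.groupby("method")["detected"]
        .agg(n_lesions="count", n_detected="sum")
        .reset_index()
    )
    per_method["detection_rate"] = per_method["n_detected"] / per_method["n_lesions"]

    table = np.array([
        [row.n_detected, row.n_lesions - row.n_detected]
        for row in per_method.itertuples()
    ])
    if table[:, 1].sum() == 0 or table[:, 0].sum() == 0 or len(methods) < 2:
        global_chi2, global_p = 0.0, 1.0
    else:
        global_chi2, global_p, _, _ = stats.chi2_contingency(table, correction=False)

    pair_rows = []
    idx = {m: i for i, m in enumerate(per_method["method"])}
    for i, ma in enumerate(methods):
        for mb in methods[i + 1:]:
            sub = table[[idx[ma], idx[mb]]]
            if sub[:, 0].sum() == 0 or sub[:, 1].sum() == 0:
                test, stat, p = "chi2", 0.0, 1.0
            else:
                expected = stats.contingency.expected_freq(sub)
                if (expected < 5).any():
                    test = "fisher"
                    _, p = stats.fisher_exact(sub)
                    stat = float("nan")
                else:
                    test = "chi2"
                    stat, p, _, _ = stats.chi2_contingency(sub, correction=False)
            pair_rows.append({"method_a": ma, "method_b": mb, "test": test,
                              "statistic": stat, "p": p})
    return DetectionTable(
        per_site=per_site,
        per_method=per_method,
        global_chi2=float(global_chi2),
        global_p=float(global_p),
        pairwise=pd.DataFrame(pair_rows),
    )


@dataclass(frozen=True)
class CutoffResult:
    """ROC summary: AUC and the optimal biomarker cutoff."""

    biomarker: str
    cutoff: float
    auc: float
    sensitivity: float
    specificity: float
    criterion: str = "youden"


def roc_optimal_cutoff(values: Sequence[float],
                       outcome: Sequence[int],
                       biomarker: str = "biomarker",
                       criterion: str = "youden") -> CutoffResult:
    """Select the optimal ROC cutoff for a biomarker against a binary outcome.

    Higher biomarker values are assumed to indicate the event.  AUC is
    the rank (Mann-Whitney) statistic with tie correction.  Candidate
    cutoffs are midpoints between consecutive distinct values; a
    patient is called positive when ``value >= cutoff``.  The cutoff
    maximises Youden's J = sensitivity + specificity - 1 (or, with
    ``criterion="closest"``, minimises the distance to the ideal (0, 1)
    ROC corner); ties are broken toward the lower cutoff.
    """
    values = np.asarray(values, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if values.shape != outcome.shape or values.ndim != 1:
        raise ValueError("values and outcome must be 1D and the same length")
    if len(np.unique(outcome)) < 2:
        raise ValueError("outcome must contain both classes")

    auc = float(roc_auc_score(outcome, values))

    distinct = np.unique(values)
    if len(distinct) == 1:
        cutoffs = distinct  # degenerate: single candidate at the value
    else:
        cutoffs = (distinct[:-1] + distinct[1:]) / 2.0
    n_pos = int(outcome.sum())
    n_neg = len(outcome) - n_pos

    best = None
    for c in cutoffs:  # ascending, so ties keep the lower cutoff
        called = values >= c
        sens = float(np.sum(called & (outcome == 1))) / n_pos
        spec = float(np.sum(~called & (outcome == 0))) / n_neg
        if criterion == "youden":
            score = sens + spec - 1.0
        elif criterion == "closest":
            score = -float(np.hypot(1.0 - sens, 1.0 - spec))
        else:
            raise ValueError(f"unknown criterion {criterion!r}")
        if best is None or score > best[0] + 1e-12:
            best = (score, c, sens, spec)
    assert best is not None
    _, cutoff, sens, spec = best
    return CutoffResult(biomarker=biomarker, cutoff=float(cutoff), auc=auc,
                        sensitivity=sens, specificity=spec, criterion=criterion)


@dataclass
class KMResult:
    """Two-group Kaplan-Meier comparison at a biomarker cutoff."""

    biomarker: str
    cutoff: float
    horizon_months: float
    survival_low: float  # S(horizon) for the < cutoff group
    survival_high: float  # S(horizon) for the >= cutoff group
    n_low: int
    n_high: int
    logrank_chi2: float
    logrank_p: float
    km_low: KaplanMeierFitter = field(repr=False, default=None)
    km_high: KaplanMeierFitter = field(repr=False, default=None)


def km_stratified(records: pd.DataFrame,
                  biomarker: str,
                  cutoff: float,
                  time_col: str = "os_time",
                  event_col: str = "os_event",
                  horizon_months: float = 60.0) -> KMResult:
    """Kaplan-Meier survival stratified at a biomarker cutoff.

    Patients with ``biomarker < cutoff`` form the low (favourable)
    group; ``>= cutoff`` the high group.  Survival at the horizon is
    read from each product-limit step function; the two groups are
    compared with the standard two-group log-rank test.
    """
    low = records[records[biomarker] < cutoff]
    high = records[records[biomarker] >= cutoff]
    if len(low) == 0 or len(high) == 0:
        raise ValueError(
            f"cutoff {cutoff} leaves an empty stratum "
            f"(n_low={len(low)}, n_high={len(high)})"
        )
    km_low = KaplanMeierFitter().fit(low[time_col], low[event_col], label="low")
    km_high = KaplanMeierFitter().fit(high[time_col], high[event_col], label="high")
    lr = logrank_test(low[time_col], high[time_col],
                      low[event_col], high[event_col])
    return KMResult(
        biomarker=biomarker,
        cutoff=float(cutoff),
        horizon_months=float(horizon_months),
        survival_low=float(km_low.predict(horizon_months)),
        survival_high=float(km_high.predict(horizon_months)),
        n_low=int(len(low)),
        n_high=int(len(high)),
        logrank_chi2=float(lr.test_statistic),
        logrank_p=float(lr.p_value),
        km_low=km_low,
        km_high=km_high,
    )


def cox_multivariate(records: pd.DataFrame,
                     endpoint: str = "OS",
                     covariates: Sequence[str] = DEFAULT_COX_COVARIATES,
                     ) -> pd.DataFrame:
    """Multivariate Cox proportional-hazards regression.

    Fits the partial likelihood (Efron handling of tied event times)
    for the chosen endpoint (``"OS"`` uses ``os_time``/``os_event``,
    ``"DFS"`` the DFS columns) on the given covariates.

    Returns
    -------
    DataFrame indexed by covariate with columns ``coef, hr, ci_lower,
    ci_upper, p`` (hazard ratios with Wald 95% CIs).

    Raises
    ------
    ValueError
        If the endpoint has no events, a covariate is constant, or the
        fit fails to converge (with the underlying diagnostic).
    """
    if endpoint not in _ENDPOINT_COLUMNS:
        raise ValueError(f"endpoint must be one of {sorted(_ENDPOINT_COLUMNS)}")
    time_col, event_col = _ENDPOINT_COLUMNS[endpoint]
    data = records[[time_col, event_col, *covariates]].copy()
    if data[event_col].sum() == 0:
        raise ValueError(f"no {endpoint} events in the cohort; cannot fit Cox model")
    constant = [c for c in covariates if data[c].nunique() <= 1]
    if constant:
        raise ValueError(f"constant covariates: {constant}")

    cph = CoxPHFitter()
    try:
        cph.fit(data, duration_col=time_col, event_col=event_col)
    except Exception as exc:  # convergence / separation diagnostics
        raise ValueError(f"Cox fit failed for {endpoint}: {exc}") from exc

    summary = cph.summary
    out = pd.DataFrame({
        "coef": summary["coef"],
        "hr": summary["exp(coef)"],
        "ci_lower": summary["exp(coef) lower 95%"],
        "ci_upper": summary["exp(coef) upper 95%"],
        "p": summary["p"],
    })
    out.index.name = "factor"
    return out
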