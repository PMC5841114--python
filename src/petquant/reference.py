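"""Published lesion accounting of a 221-patient post-therapy NPC cohort.

These counts are the printed site-level lesion tallies and per-method
segmentation-failure totals of a retrospective whole-body FDG-PET
cohort of nasopharyngeal-carcinoma patients after comprehensive
therapy.  They serve as fixed inputs for detection-rate accounting:
per-site lesion counts, the number of lesions each threshold method
failed to segment, and the cohort's demographic composition.
"""

from __future__ import annotations

import pandas as pd

from petquant.segmentation import ThresholdMethod

__all__ = [
    "LESIONS_PER_SITE",
    "UNDETECTED_PER_SITE",
    "COHORT_COMPOSITION",
    "reference_lesion_statuses",
]

#: Definitive lesions per anatomical site (576 total).
LESIONS_PER_SITE = {
    "nasopharynx": 86,
    "skull_base": 92,
    "lymph_node": 278,
    "pleura": 3,
    "lung": 36,
    "liver": 20,
    "bone": 61,
}

#: Lesions each threshold method failed to segment, per site.
UNDETECTED_PER_SITE = {
    ThresholdMethod.TH2_5: {
        "nasopharynx": 31, "skull_base": 38, "lymph_node": 58,
        "pleura": 0, "lung": 28, "liver": 11, "bone": 32,
    },
    ThresholdMethod.TH20: {
        "nasopharynx": 25, "skull_base": 11, "lymph_node": 28,
        "pleura": 0, "lung": 18, "liver": 7, "bone": 25,
    },
    ThresholdMethod.TH40: {
        "nasopharynx": 28, "skull_base": 29, "lymph_node": 41,
        "pleura": 0, "lung": 25, "liver": 9, "bone": 32,
    },
    ThresholdMethod.THBGD: {
        "nasopharynx": 2, "skull_base": 5, "lymph_node": 15,
        "pleura": 0, "lung": 11, "liver": 6, "bone": 16,
    },
}

#: Cohort demographics: counts of 221 patients.
COHORT_COMPOSITION = {
    "n_patients": 221,
    "male": 169,
    "female": 52,
    "treatment": {
        "radiotherapy": 89,
        "radiotherapy_chemotherapy": 119,
        "surgery_radiotherapy_chemotherapy": 10,
        "surgery_radiotherapy": 1,
        "chemotherapy": 1,
        "surgery": 1,
    },
    "status": {"no_evidence_of_disease": 156, "alive_with_disease": 28, "dead": 37},
}


def reference_lesion_statuses() -> pd.DataFrame:
    """Expand the published counts to per-lesion detection statuses.

    Returns a long-format DataFrame (one row per lesion x method) with
    columns ``lesion_id, site, method, detected``, suitable for
    :func:`petquant.cohort_stats.detection_rate_table`.  Within a site
    the undetected lesions of each method are assigned to the first
    rows; per-method totals and rates are unaffected by this choice.
    """
    rows = []
    lesion_idx = 0
    for site, n_site in LESIONS_PER_SITE.items():
        for i in range(n_site):
            lesion_id = f"ref{lesion_idx:03d}"
            lesion_idx += 1
            for method in ThresholdMethod:
                n_undet = UNDETECTED_PER_SITE[method][site]
                rows.append({
                    "lesion_id": lesion_id,
                    "site": site,
                    "method": method.value,
                    "detected": i >= n_undet,
                })
    return pd.DataFrame(rows)
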