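"""End-to-end helpers: segment all lesions, quantify, aggregate.

These functions are the library surface the command-line interface and
the analysis drivers share.
"""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from petquant.image_io import LesionAnnotation, SUVImage
from petquant.quantify import aggregate_whole_body, lesion_metrics
from petquant.segmentation import ThresholdMethod, segment_lesion

__all__ = ["segment_all", "patient_summary", "ALL_METHODS"]

ALL_METHODS = tuple(ThresholdMethod)


def segment_all(image: SUVImage,
                annotations: Sequence[LesionAnnotation],
                methods: Sequence[ThresholdMethod] = ALL_METHODS,
                rng_seed: int = 0,
                patient_id: Optional[str] = None,
                **segment_kwargs) -> pd.DataFrame:
    """Segment every lesion with every method and compute lesion metrics.

    Returns a long-format DataFrame (one row per lesion x method) with
    columns ``lesion_id, site, method, threshold_suv, status, detected,
    n_voxels, mtv, suvmax, suvmean, tlg``.
    """
    rows = []
    for ann in annotations:
        for method in methods:
            res = segment_lesion(image, ann, method, annotations,
                                 rng_seed=rng_seed, **segment_kwargs)
            met = lesion_metrics(image, res, patient_id=patient_id)
            rows.append({
                "lesion_id": ann.lesion_id,
                "site": ann.site,
                "method": method.value,
                "threshold_suv": res.threshold_suv,
                "status": res.status.value,
                "detected": res.detected,
                "n_voxels": res.n_voxels,
                "mtv": met.mtv,
                "suvmax": met.suvmax,
                "suvmean": met.suvmean,
                "tlg": met.tlg,
            })
    return pd.DataFrame(rows, columns=[
        "lesion_id", "site", "method", "threshold_suv", "status", "detected",
        "n_voxels", "mtv", "suvmax", "suvmean", "tlg",
    ])


def patient_summary(per_lesion: pd.DataFrame,
                    patient_id: str = "patient") -> pd.DataFrame:
    """Aggregate a per-lesion table to whole-body totals per method.

    Returns one row per method: ``patient_id, method, lesion_count,
    detected_count, wbmtv, wbtlg, suvmax``.
    """
    rows = []
    for method, grp in per_lesion.groupby("method", sort=False):
        detected = grp[grp["detected"]]
        rows.append({
            "patient_id": patient_id,
            "method": method,
            "lesion_count": len(grp),
            "detected_count": len(detected),
            "wbmtv": float(detected["mtv"].sum()),
            "wbtlg": float(detected["tlg"].sum()),
            "suvmax": float(grp["suvmax"].max()) if len(grp) else 0.0,
        })
    return pd.DataFrame(rows)
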