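"""Per-lesion and whole-body metabolic metrics.

MTV is the segmented volume in cm^3 (voxel count x voxel volume; for a
voxelised mask this is identical to summing per-slice area x slice
thickness).  TLG = MTV x SUVmean.  Whole-body totals (WBMTV, WBTLG) sum
over a patient's detected lesions; lesions that could not be segmented
(EMPTY or LEAKED) contribute zero by default and carry an ``excluded``
flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from petquant.image_io import SUVImage
from petquant.segmentation import SegmentationResult, SegmentationStatus

__all__ = ["LesionMetrics", "PatientMetrics", "lesion_metrics", "aggregate_whole_body"]


@dataclass(frozen=True)
class LesionMetrics:
    """MTV (cm^3), SUVmax, SUVmean and TLG (SUV*cm^3) of one lesion."""

    lesion_id: str
    mtv: float
    suvmax: float
    suvmean: float
    tlg: float
    excluded: bool = False
    patient_id: Optional[str] = None


@dataclass(frozen=True)
class PatientMetrics:
    """Whole-body totals for one patient.

    WBMTV and WBTLG are sums of MTV and TLG over the patient's detected
    lesions; SUVmax is the maximum lesion SUVmax.
    """

    patient_id: str
    wbmtv: float
    wbtlg: float
    suvmax: float
    lesion_count: int
    detected_count: int


def lesion_metrics(image: SUVImage,
                   result: SegmentationResult,
                   patient_id: Optional[str] = None) -> LesionMetrics:
    """Compute MTV, SUVmean, SUVmax and TLG for one segmented lesion.

    EMPTY and LEAKED lesions get MTV = TLG = 0 and ``excluded=True``;
    their SUVmax is still reported (it is read at the seed voxel, not
    from the mask).
    """
    if result.status is not SegmentationStatus.DETECTED:
        return LesionMetrics(
            lesion_id=result.lesion_id,
            mtv=0.0,
            suvmax=result.suvmax_lesion,
            suvmean=0.0,
            tlg=0.0,
            excluded=True,
            patient_id=patient_id,
        )
    mask = np.asarray(result.mask)
    values = image.voxels[mask[:, 0], mask[:, 1], mask[:, 2]]
    mtv = len(mask) * image.voxel_volume_cm3
    suvmean = float(values.mean())
    return LesionMetrics(
        lesion_id=result.lesion_id,
        mtv=float(mtv),
        suvmax=float(values.max()),
        suvmean=suvmean,
        tlg=float(mtv * suvmean),
        excluded=False,
        patient_id=patient_id,
    )


def aggregate_whole_body(metrics: Sequence[LesionMetrics],
                         patient_id: Optional[str] = None) -> PatientMetrics:
    """Aggregate lesion metrics to whole-body totals for one patient.

    WBMTV = sum of MTVs and WBTLG = sum of TLGs over non-excluded
    lesions; SUVmax is the maximum over all lesions.  An empty list
    yields all-zero totals.
    """
    ids = {m.patient_id for m in metrics if m.patient_id is not None}
    if len(ids) > 1:
        raise ValueError(f"metrics from multiple patients: {sorted(ids)}")
    if patient_id is None:
        patient_id = ids.pop() if ids else ""

    detected = [m for m in metrics if not m.excluded]
    return PatientMetrics(
        patient_id=patient_id,
        wbmtv=float(sum(m.mtv for m in detected)),
        wbtlg=float(sum(m.tlg for m in detected)),
        suvmax=float(max((m.suvmax for m in metrics), default=0.0)),
        lesion_count=len(metrics),
        detected_count=len(detected),
    )
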