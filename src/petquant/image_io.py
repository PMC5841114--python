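"""Image volumes, annotations, and SUV conversion.

Conventions
-----------
* Voxel arrays are indexed ``(x, y, z)``; ``spacing`` stores the voxel
  edge length in mm per axis in the same order.
* Voxel indices are 0-based; bounding boxes are half-open ``[lo, hi)``
  per axis.
* SUV is the body-weight variant: activity concentration normalised by
  injected dose per body weight, dimensionless under the convention
  1 kg of tissue occupies approximately 1000 mL.
* Decay correction is assumed to have been applied upstream; the
  acquisition metadata only records whether it was.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "SITE_LABELS",
    "AcquisitionMeta",
    "SUVImage",
    "LesionAnnotation",
    "suv_from_activity",
    "read_suv_volume",
    "write_suv_volume",
    "read_annotations",
    "write_annotations",
]

#: Anatomical-site vocabulary for lesion annotations (nasopharyngeal
#: carcinoma recurrence/metastasis sites).
SITE_LABELS = (
    "nasopharynx",
    "skull_base",
    "lymph_node",
    "pleura",
    "lung",
    "liver",
    "bone",
)


class InvalidMetadataError(ValueError):
    """Acquisition metadata is unusable for SUV conversion."""


@dataclass(frozen=True)
class AcquisitionMeta:
    """Injection metadata needed for body-weight SUV conversion.

    Parameters
    ----------
    injected_dose : float
        Injected activity in MBq, decay-corrected to scan time upstream.
    body_weight : float
        Patient body weight in kg.
    decay_corrected : bool
        Whether the activity volume was already decay-corrected to
        injection time. Recorded, not acted upon.
    """

    injected_dose: float
    body_weight: float
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        if not (self.injected_dose > 0):
            raise InvalidMetadataError(
                f"injected_dose must be > 0 MBq, got {self.injected_dose!r}"
            )
        if not (self.body_weight > 0):
            raise InvalidMetadataError(
                f"body_weight must be > 0 kg, got {self.body_weight!r}"
            )


@dataclass
class SUVImage:
    """A 3D grid of SUV values with physical voxel spacing.

    Attributes
    ----------
    voxels : ndarray, shape (nx, ny, nz)
        Dimensionless SUV values, finite and non-negative.
    spacing : tuple of 3 floats
        Voxel edge lengths in mm, ordered (x, y, z).
    origin : tuple of 3 floats
        Physical coordinate (mm) of voxel (0, 0, 0).
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be 3D, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel values must be finite")
        if np.any(self.voxels < 0):
            raise ValueError("voxel values must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (product of spacings / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class LesionAnnotation:
    """One lesion's search region: site label, bounding box, optional seed.

    ``bbox`` is a half-open voxel box ``((x0, x1), (y0, y1), (z0, z1))``;
    the optional ``seed`` voxel index must lie inside it.
    """

    lesion_id: str
    site: str
    bbox: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    seed: Optional[tuple[int, int, int]] = None

    def __post_init__(self) -> None:
        if self.site not in SITE_LABELS:
            raise ValueError(
                f"unknown site {self.site!r} for lesion {self.lesion_id!r}; "
                f"allowed: {', '.join(SITE_LABELS)}"
            )
        bbox = tuple(tuple(int(v) for v in ax) for ax in self.bbox)
        if len(bbox) != 3 or any(len(ax) != 2 for ax in bbox):
            raise ValueError(f"bbox must be 3 (lo, hi) pairs, got {self.bbox!r}")
        if any(hi <= lo for lo, hi in bbox):
            raise ValueError(
                f"bbox {bbox} of lesion {self.lesion_id!r} is empty (half-open [lo, hi))"
            )
        object.__setattr__(self, "bbox", bbox)
        if self.seed is not None:
            seed = tuple(int(v) for v in self.seed)
            if len(seed) != 3:
                raise ValueError(f"seed must have 3 components, got {self.seed!r}")
            if any(not (lo <= s < hi) for s, (lo, hi) in zip(seed, bbox)):
                raise ValueError(
                    f"seed {seed} of lesion {self.lesion_id!r} outside bbox {bbox}"
                )
            object.__setattr__(self, "seed", seed)

    def validate_against(self, image: SUVImage) -> None:
        """Raise if the bounding box exceeds the image bounds."""
        for (lo, hi), n in zip(self.bbox, image.shape):
            if lo < 0 or hi > n:
                raise ValueError(
                    f"bbox {self.bbox} of lesion {self.lesion_id!r} outside "
                    f"image of shape {image.shape}"
                )


def suv_from_activity(activity_concentration: np.ndarray | SUVImage,
                      meta: AcquisitionMeta,
                      spacing: Sequence[float] | None = None,
                      origin: Sequence[float] | None = None) -> SUVImage:
    """Convert an activity-concentration volume (kBq/mL) to body-weight SUV.

    SUV = activity[kBq/mL] * body_weight[kg] / injected_dose[MBq]; the
    kBq/MBq factor cancels against the 1 kg ~ 1000 mL tissue-density
    convention, so the result is dimensionless.
    """
    if isinstance(activity_concentration, SUVImage):
        conc = activity_concentration.voxels
        spacing = activity_concentration.spacing
        origin = activity_concentration.origin
    else:
        conc = np.asarray(activity_concentration, dtype=np.float64)
        if spacing is None:
            spacing = (1.0, 1.0, 1.0)
        if origin is None:
            origin = (0.0, 0.0, 0.0)
    if np.any(conc < 0):
        raise ValueError("activity concentration must be non-negative")
    suv = conc * (meta.body_weight / meta.injected_dose)
    return SUVImage(voxels=suv, spacing=tuple(spacing), origin=tuple(origin))


def _affine_from(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def write_suv_volume(image: SUVImage, path: str | Path) -> None:
    """Write an :class:`SUVImage` as NIfTI (.nii or .nii.gz).

    Voxel data are stored as float32 in (x, y, z) order with a diagonal
    affine carrying spacing and origin.
    """
    img = nib.Nifti1Image(
        image.voxels.astype(np.float32),
        _affine_from(image.spacing, image.origin),
    )
    img.header.set_zooms(image.spacing)
    nib.save(img, str(path))


def read_suv_volume(path: str | Path, format: str = "nifti") -> SUVImage:
    """Read an SUV volume from a NIfTI file or a DICOM series directory.

    Parameters
    ----------
    path : str or Path
        NIfTI file (``format="nifti"``) or a directory containing one
        DICOM series (``format="dicom-series"``).
    format : {"nifti", "dicom-series"}

    Returns
    -------
    SUVImage
        Voxels in (x, y, z) order; round-trips with
        :func:`write_suv_volume` up to float32 precision, spacing exact.
    """
    if format == "nifti":
        return _read_nifti(Path(path))
    if format == "dicom-series":
        return _read_dicom_series(Path(path))
    raise ValueError(f"unknown format {format!r}; use 'nifti' or 'dicom-series'")


def _read_nifti(path: Path) -> SUVImage:
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    if any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise ValueError(f"missing or invalid voxel spacing in {path}: {zooms}")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return SUVImage(voxels=data, spacing=tuple(float(z) for z in zooms), origin=origin)


def _read_dicom_series(directory: Path) -> SUVImage:
    import pydicom

    if not directory.is_dir():
        raise FileNotFoundError(f"{directory} is not a directory")
    files = sorted(p for p in directory.iterdir() if p.is_file())
    datasets = [pydicom.dcmread(str(p)) for p in files]
    if not datasets:
        raise ValueError(f"no DICOM files in {directory}")

    orientations = {tuple(round(float(v), 6) for v in ds.ImageOrientationPatient)
                    for ds in datasets}
    if len(orientations) != 1:
        raise ValueError(f"mixed-orientation DICOM series in {directory}")
    row, col = np.array(datasets[0].ImageOrientationPatient, dtype=float).reshape(2, 3)
    normal = np.cross(row, col)

    datasets.sort(key=lambda ds: float(np.dot(normal, np.array(ds.ImagePositionPatient, dtype=float))))
    positions = np.array([np.dot(normal, np.array(ds.ImagePositionPatient, dtype=float))
                          for ds in datasets])
    if len(datasets) < 2:
        raise ValueError("DICOM series must contain at least two slices")
    steps = np.diff(positions)
    if np.ptp(steps) > 1e-3 or steps[0] <= 0:
        raise ValueError("inconsistent DICOM slice spacing")
    dz = float(steps[0])
    try:
        dy, dx = (float(v) for v in datasets[0].PixelSpacing)
    except AttributeError as exc:
        raise ValueError(f"missing PixelSpacing in DICOM series {directory}") from exc

    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    # pixel_array rows are y, columns are x; stack slices along z.
    vol = np.stack(slices, axis=-1).transpose(1, 0, 2)
    origin = tuple(float(v) for v in datasets[0].ImagePositionPatient)
    return SUVImage(voxels=vol, spacing=(dx, dy, dz), origin=origin)


def write_annotations(annotations: Sequence[LesionAnnotation], path: str | Path) -> None:
    """Write lesion annotations to a JSON file."""
    records = []
    for ann in annotations:
        rec: dict = {
            "lesion_id": ann.lesion_id,
            "site": ann.site,
            "bbox": [list(ax) for ax in ann.bbox],
        }
        if ann.seed is not None:
            rec["seed"] = list(ann.seed)
        records.append(rec)
    Path(path).write_text(json.dumps(records, indent=2))


def read_annotations(path: str | Path,
                     image: Optional[SUVImage] = None) -> list[LesionAnnotation]:
    """Read lesion annotations from JSON or CSV.

    JSON: a list of objects ``{lesion_id, site, bbox: [[x0,x1],[y0,y1],
    [z0,z1]], seed?: [x,y,z]}``. CSV: columns ``lesion_id, site, x0, x1,
    y0, y1, z0, z1`` and optional ``seed_x, seed_y, seed_z``.

    When ``image`` is supplied every bounding box is validated against
    its bounds.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".csv":
        raw = _annotation_rows_from_csv(path)
    else:
        raw = _annotation_rows_from_json(path)

    annotations = []
    for i, rec in enumerate(raw):
        try:
            annotations.append(LesionAnnotation(**rec))
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed annotation row {i} in {path}: {exc}") from exc
    if image is not None:
        for ann in annotations:
            ann.validate_against(image)
    return annotations


def _annotation_rows_from_json(path: Path) -> list[dict]:
    data = json.loads(path.read_text())
    if not isinstance(data, list):
        raise ValueError(f"annotation JSON {path} must contain a list")
    rows = []
    for rec in data:
        row = {
            "lesion_id": str(rec["lesion_id"]),
            "site": rec["site"],
            "bbox": tuple(tuple(ax) for ax in rec["bbox"]),
        }
        if rec.get("seed") is not None:
            row["seed"] = tuple(rec["seed"])
        rows.append(row)
    return rows


def _annotation_rows_from_csv(path: Path) -> list[dict]:
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            row = {
                "lesion_id": rec["lesion_id"],
                "site": rec["site"],
                "bbox": (
                    (int(rec["x0"]), int(rec["x1"])),
                    (int(rec["y0"]), int(rec["y1"])),
                    (int(rec["z0"]), int(rec["z1"])),
                ),
            }
            if rec.get("seed_x") not in (None, ""):
                row["seed"] = (int(rec["seed_x"]), int(rec["seed_y"]), int(rec["seed_z"]))
            rows.append(row)
    return rows
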