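"""Threshold-based 3D lesion segmentation.

Four delineation rules are supported, all applied with a strict
``SUV > threshold`` predicate:

* ``TH2_5``  — absolute threshold at SUV 2.5;
* ``TH20``   — 20% of the lesion SUVmax;
* ``TH40``   — 40% of the lesion SUVmax;
* ``THBGD``  — background-relative: SUVbgd + 20% * (SUVmax - SUVbgd),
  where SUVbgd is the mean of the maximum SUVs of ten randomly placed
  spherical background regions around the lesion.

Each lesion is grown from its hottest voxel (or an annotated seed) as
the 6-connected super-threshold component inside its bounding box
dilated by a leak margin.  A component that reaches the dilated
boundary has merged with surrounding background and is classified
``LEAKED``; an empty component is ``EMPTY``; only ``DETECTED`` lesions
count as segmentable.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from petquant.image_io import LesionAnnotation, SUVImage

__all__ = [
    "ThresholdMethod",
    "LesionAnnotation",
    "BackgroundEstimate",
    "SegmentationStatus",
    "SegmentationResult",
    "ThresholdWarning",
    "compute_threshold",
    "estimate_background",
    "region_grow",
    "segment_lesion",
]


class ThresholdMethod(enum.Enum):
    """Delineation rule for the lesion-segmentation threshold."""

    TH2_5 = "th2.5"
    TH20 = "th20"
    TH40 = "th40"
    THBGD = "thbgd"

    @property
    def needs_background(self) -> bool:
        return self is ThresholdMethod.THBGD


#: Parameters of the threshold rules: absolute SUV level for TH2_5,
#: SUVmax fractions for TH20/TH40, and the background fraction for THBGD.
ABSOLUTE_LEVEL = 2.5
FRACTION = {
    ThresholdMethod.TH20: 0.20,
    ThresholdMethod.TH40: 0.40,
    ThresholdMethod.THBGD: 0.20,
}


class ThresholdWarning(UserWarning):
    """The computed threshold cannot select any lesion voxel."""


class SegmentationStatus(enum.Enum):
    DETECTED = "DETECTED"
    EMPTY = "EMPTY"
    LEAKED = "LEAKED"


@dataclass(frozen=True)
class BackgroundEstimate:
    """Background SUV around a lesion.

    ``suv_bgd`` is the arithmetic mean of the per-region maximum SUV
    over ``region_centers`` spherical regions of ``region_radius``
    voxels placed in a shell around the lesion.
    """

    suv_bgd: float
    region_centers: tuple[tuple[int, int, int], ...]
    region_radius: float

    def __post_init__(self) -> None:
        if self.suv_bgd < 0:
            raise ValueError("suv_bgd must be >= 0")


@dataclass
class SegmentationResult:
    """Outcome of segmenting one lesion with one threshold method."""

    lesion_id: str
    method: ThresholdMethod
    threshold_suv: float
    mask: np.ndarray  # (k, 3) int voxel indices; empty for EMPTY status
    status: SegmentationStatus
    seed: tuple[int, int, int]
    suvmax_lesion: float
    background: Optional[BackgroundEstimate] = None

    @property
    def detected(self) -> bool:
        return self.status is SegmentationStatus.DETECTED

    @property
    def n_voxels(self) -> int:
        return int(len(self.mask))


def compute_threshold(method: ThresholdMethod,
                      suvmax_lesion: float,
                      suv_bgd: Optional[float] = None) -> float:
    """Compute the segmentation threshold SUV for one lesion.

    Parameters
    ----------
    method : ThresholdMethod
    suvmax_lesion : float
        Maximum SUV of the lesion (must be > 0).
    suv_bgd : float, optional
        Background SUV; required for ``THBGD`` only.

    Returns
    -------
    float
        TH2_5 -> 2.5; TH20 -> 0.20*SUVmax; TH40 -> 0.40*SUVmax;
        THBGD -> SUVbgd + 0.20*(SUVmax - SUVbgd).

    Warns
    -----
    ThresholdWarning
        For THBGD when ``suv_bgd > suvmax_lesion``: the threshold then
        exceeds SUVmax and segmentation will be EMPTY under the strict
        ``>`` rule.
    """
    if not (suvmax_lesion > 0):
        raise ValueError(f"suvmax_lesion must be > 0, got {suvmax_lesion}")
    if method is ThresholdMethod.TH2_5:
        return ABSOLUTE_LEVEL
    if method in (ThresholdMethod.TH20, ThresholdMethod.TH40):
        return FRACTION[method] * suvmax_lesion
    if method is ThresholdMethod.THBGD:
        if suv_bgd is None:
            raise ValueError("THBGD requires a background SUV estimate")
        if suv_bgd > suvmax_lesion:
            warnings.warn(
                f"background SUV {suv_bgd:.3g} exceeds lesion SUVmax "
                f"{suvmax_lesion:.3g}; threshold exceeds SUVmax and the "
                "segmentation will be empty",
                ThresholdWarning,
                stacklevel=2,
            )
        return suv_bgd + FRACTION[method] * (suvmax_lesion - suv_bgd)
    raise ValueError(f"unknown method {method!r}")


def _sphere_offsets(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    ax = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(ax, ax, ax, indexing="ij")
    inside = dx**2 + dy**2 + dz**2 <= radius**2
    return np.stack([dx[inside], dy[inside], dz[inside]], axis=1)


def _boxes_overlap(center: np.ndarray, radius: float,
                   bbox: Sequence[Sequence[int]]) -> bool:
    """True if a sphere (voxel units) intersects a half-open voxel box."""
    # distance from center to the closest point of the box
    lo = np.array([ax[0] for ax in bbox], dtype=float)
    hi = np.array([ax[1] - 1 for ax in bbox], dtype=float)
    closest = np.clip(center, lo, hi)
    return float(np.sum((center - closest) ** 2)) <= radius**2


def estimate_background(image: SUVImage,
                        lesion: LesionAnnotation,
                        all_lesions: Sequence[LesionAnnotation] = (),
                        n_regions: int = 10,
                        region_radius: float = 2.0,
                        shell: tuple[float, float] = (1.0, 5.0),
                        rng_seed: int = 0,
                        max_tries: int = 10_000) -> BackgroundEstimate:
    """Estimate the background SUV around a lesion.

    ``n_regions`` spherical regions of ``region_radius`` voxels are
    placed at seeded-random, mutually non-overlapping centers in a
    shell ``shell[0]``..``shell[1]`` voxels outside the lesion bounding
    box, rejecting positions that intersect any lesion bounding box or
    fall outside the image.  The per-region statistic is the region's
    maximum SUV; ``suv_bgd`` is the mean of the per-region maxima.

    Deterministic given ``rng_seed``.
    """
    lesion.validate_against(image)
    rng = np.random.default_rng(rng_seed)
    inner, outer = shell
    if not (0 <= inner < outer):
        raise ValueError(f"invalid shell {shell}")

    lo = np.array([ax[0] for ax in lesion.bbox])
    hi = np.array([ax[1] for ax in lesion.bbox])
    shape = np.array(image.shape)

    # candidate centers: integer voxels in the dilated box minus the
    # inner-dilated box, fully inside the image
    grow_lo = np.maximum(lo - int(np.ceil(outer)), 0)
    grow_hi = np.minimum(hi + int(np.ceil(outer)), shape)
    exclusions = list(all_lesions) if all_lesions else [lesion]
    if lesion not in exclusions:
        exclusions.append(lesion)

    offsets = _sphere_offsets(region_radius)
    centers: list[np.ndarray] = []
    for _ in range(max_tries):
        if len(centers) == n_regions:
            break
        cand = np.array([rng.integers(a, b) for a, b in zip(grow_lo, grow_hi)])
        # must lie in the shell: outside the inner-dilated lesion box
        inner_box = [(ax[0] - inner, ax[1] + inner) for ax in lesion.bbox]
        if _point_in_box(cand, inner_box):
            continue
        # sphere fully inside image
        if np.any(cand - region_radius < 0) or np.any(cand + region_radius > shape - 1):
            continue
        # must not touch any lesion bbox
        if any(_boxes_overlap(cand.astype(float), region_radius, les.bbox)
               for les in exclusions):
            continue
        # non-overlapping with already placed regions
        if any(np.sum((cand - c) ** 2) < (2 * region_radius) ** 2 for c in centers):
            continue
        centers.append(cand)
    if len(centers) < n_regions:
        raise ValueError(
            f"insufficient eligible background voxels around lesion "
            f"{lesion.lesion_id!r}: placed {len(centers)}/{n_regions} regions"
        )

    maxima = []
    for c in centers:
        vox = offsets + c
        maxima.append(float(image.voxels[vox[:, 0], vox[:, 1], vox[:, 2]].max()))
    return BackgroundEstimate(
        suv_bgd=float(np.mean(maxima)),
        region_centers=tuple(tuple(int(v) for v in c) for c in centers),
        region_radius=float(region_radius),
    )


def _point_in_box(p: np.ndarray, bbox: Sequence[Sequence[float]]) -> bool:
    return all(lo <= v < hi for v, (lo, hi) in zip(p, bbox))


def region_grow(image: SUVImage,
                seed: tuple[int, int, int],
                threshold_suv: float,
                bounds: Sequence[Sequence[int]],
                leak_margin: int = 3) -> tuple[np.ndarray, bool]:
    """Grow the 6-connected super-threshold region containing ``seed``.

    The growth domain is ``bounds`` (half-open per axis) dilated by
    ``leak_margin`` voxels and clipped to the image.  The mask is the
    6-connected component of ``{v : SUV(v) > threshold_suv}`` within
    that domain that contains the seed; ``leaked`` is True iff the
    component touches the outer face of the dilated domain.

    Returns
    -------
    mask : ndarray of shape (k, 3)
        Voxel indices of the component; empty if the seed itself is not
        above threshold.
    leaked : bool
    """
    seed = tuple(int(v) for v in seed)
    if any(not (lo <= s < hi) for s, (lo, hi) in zip(seed, bounds)):
        raise ValueError(f"seed {seed} outside bounds {bounds}")
    shape = image.shape
    lo = np.array([max(ax[0] - leak_margin, 0) for ax in bounds])
    hi = np.array([min(ax[1] + leak_margin, n) for ax, n in zip(bounds, shape)])

    sub = image.voxels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    above = sub > threshold_suv
    seed_local = tuple(np.array(seed) - lo)
    if not above[seed_local]:
        return np.empty((0, 3), dtype=np.intp), False

    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    labels, _ = ndimage.label(above, structure=structure)
    comp = labels == labels[seed_local]
    coords = np.argwhere(comp)

    leaked = bool(
        np.any(coords == 0) or np.any(coords == (hi - lo - 1))
    )
    return coords + lo, leaked


def segment_lesion(image: SUVImage,
                   lesion: LesionAnnotation,
                   method: ThresholdMethod,
                   all_lesions: Sequence[LesionAnnotation] = (),
                   rng_seed: int = 0,
                   leak_margin: int = 3,
                   n_background_regions: int = 10,
                   background_region_radius: float = 2.0,
                   background_shell: tuple[float, float] = (1.0, 5.0),
                   ) -> SegmentationResult:
    """Segment one lesion with one threshold method.

    The seed is the annotated seed if given, otherwise the hottest voxel
    inside the bounding box (ties broken by lowest linear index).  For
    ``THBGD`` the background SUV is estimated first.  The lesion counts
    as segmentable iff the result status is ``DETECTED``.
    """
    lesion.validate_against(image)
    (x0, x1), (y0, y1), (z0, z1) = lesion.bbox
    box = image.voxels[x0:x1, y0:y1, z0:z1]
    if lesion.seed is not None:
        seed = lesion.seed
    else:
        flat = int(np.argmax(box))  # lowest linear index wins ties
        local = np.unravel_index(flat, box.shape)
        seed = (x0 + int(local[0]), y0 + int(local[1]), z0 + int(local[2]))
    suvmax_lesion = float(image.voxels[seed])

    background = None
    if method.needs_background:
        background = estimate_background(
            image, lesion, all_lesions,
            n_regions=n_background_regions,
            region_radius=background_region_radius,
            shell=background_shell,
            rng_seed=rng_seed,
        )
        threshold = compute_threshold(method, suvmax_lesion, background.suv_bgd)
    else:
        threshold = compute_threshold(method, suvmax_lesion)

    mask, leaked = region_grow(image, seed, threshold, lesion.bbox,
                               leak_margin=leak_margin)
    if len(mask) == 0:
        status = SegmentationStatus.EMPTY
    elif leaked:
        status = SegmentationStatus.LEAKED
    else:
        status = SegmentationStatus.DETECTED
    return SegmentationResult(
        lesion_id=lesion.lesion_id,
        method=method,
        threshold_suv=float(threshold),
        mask=mask,
        status=status,
        seed=seed,
        suvmax_lesion=suvmax_lesion,
        background=background,
    )
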