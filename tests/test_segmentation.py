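import numpy as np
import pytest

from petquant.image_io import LesionAnnotation, SUVImage
from petquant.phantom import LesionSpec, PhantomSpec, generate_phantom
from petquant.segmentation import (
    SegmentationStatus,
    ThresholdMethod,
    ThresholdWarning,
    compute_threshold,
    estimate_background,
    region_grow,
    segment_lesion,
)
from conftest import flood_fill_6


class TestComputeThreshold:
    @pytest.mark.parametrize("method,suvmax,suvbgd,expected", [
        (ThresholdMethod.TH2_5, 17.3, None, 2.5),
        (ThresholdMethod.TH2_5, 3.0, None, 2.5),
        (ThresholdMethod.TH40, 10.0, None, 4.0),
        (ThresholdMethod.TH20, 10.0, None, 2.0),
        (ThresholdMethod.THBGD, 10.0, 1.0, 2.8),  # 1 + 0.2 * 9
        (ThresholdMethod.THBGD, 4.0, 4.0, 4.0),  # degenerate fixed point
    ])
    def test_closed_forms(self, method, suvmax, suvbgd, expected):
        assert compute_threshold(method, suvmax, suvbgd) == pytest.approx(expected)

    def test_thbgd_requires_background(self):
        with pytest.raises(ValueError, match="background"):
            compute_threshold(ThresholdMethod.THBGD, 5.0)

    def test_background_above_suvmax_warns(self):
        with pytest.warns(ThresholdWarning):
            t = compute_threshold(ThresholdMethod.THBGD, 2.0, 3.0)
        assert t > 2.0  # threshold exceeds SUVmax -> EMPTY downstream

    def test_nonpositive_suvmax_rejected(self):
        with pytest.raises(ValueError):
            compute_threshold(ThresholdMethod.TH40, 0.0)

    def test_randomized_against_arithmetic_oracle(self, rng):
        for _ in range(200):
            suvmax = rng.uniform(0.5, 30.0)
            suvbgd = rng.uniform(0.0, suvmax)
            assert compute_threshold(ThresholdMethod.TH20, suvmax) == \
                pytest.approx(0.20 * suvmax)
            assert compute_threshold(ThresholdMethod.TH40, suvmax) == \
                pytest.approx(0.40 * suvmax)
            th = compute_threshold(ThresholdMethod.THBGD, suvmax, suvbgd)
            assert th == pytest.approx(suvbgd + 0.20 * (suvmax - suvbgd))
            assert suvbgd - 1e-12 <= th <= suvmax + 1e-12


class TestEstimateBackground:
    def _lesion(self):
        return LesionAnnotation("L0", "lung", ((12, 18), (12, 18), (12, 18)))

    def test_uniform_background_recovered_exactly(self):
        image = SUVImage(np.full((30, 30, 30), 1.7), spacing=(1, 1, 1))
        est = estimate_background(image, self._lesion(), rng_seed=3)
        assert est.suv_bgd == pytest.approx(1.7)
        assert len(est.region_centers) == 10

    def test_deterministic_given_seed(self):
        image = SUVImage(np.full((30, 30, 30), 1.0), spacing=(1, 1, 1))
        a = estimate_background(image, self._lesion(), rng_seed=5)
        b = estimate_background(image, self._lesion(), rng_seed=5)
        assert a.region_centers == b.region_centers
        assert a.suv_bgd == b.suv_bgd

    def test_matches_brute_force_region_maxima(self, rng):
        # planted hot voxels: recompute each region's max by exhaustive scan
        vox = rng.uniform(0.5, 1.5, size=(30, 30, 30))
        vox[rng.integers(0, 30, 40), rng.integers(0, 30, 40),
            rng.integers(0, 30, 40)] += rng.uniform(0, 3, 40)
        image = SUVImage(vox, spacing=(1, 1, 1))
        est = estimate_background(image, self._lesion(), rng_seed=11)
        maxima = []
        r = est.region_radius
        for cx, cy, cz in est.region_centers:
            best = -np.inf
            for x in range(vox.shape[0]):
                for y in range(vox.shape[1]):
                    for z in range(vox.shape[2]):
                        if (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= r ** 2:
                            best = max(best, vox[x, y, z])
            maxima.append(best)
        assert est.suv_bgd == pytest.approx(np.mean(maxima))

    def test_regions_avoid_all_lesion_boxes(self):
        image = SUVImage(np.ones((30, 30, 30)), spacing=(1, 1, 1))
        other = LesionAnnotation("L1", "bone", ((20, 28), (20, 28), (20, 28)))
        est = estimate_background(image, self._lesion(), [self._lesion(), other],
                                  rng_seed=2)
        r = est.region_radius
        for c in est.region_centers:
            for box in (self._lesion().bbox, other.bbox):
                lo = np.array([ax[0] for ax in box]) - r
                hi = np.array([ax[1] - 1 for ax in box]) + r
                assert not all(lo[i] <= c[i] <= hi[i] for i in range(3)) or \
                    np.sum((np.clip(c, [ax[0] for ax in box],
                                    [ax[1] - 1 for ax in box]) -
                            np.array(c)) ** 2) > r ** 2

    def test_insufficient_room_raises_with_lesion_id(self):
        image = SUVImage(np.ones((8, 8, 8)), spacing=(1, 1, 1))
        lesion = LesionAnnotation("tight", "liver", ((0, 8), (0, 8), (0, 8)))
        with pytest.raises(ValueError, match="tight"):
            estimate_background(image, lesion, rng_seed=0, max_tries=500)


class TestRegionGrow:
    def test_single_voxel_island(self):
        vox = np.zeros((9, 9, 9))
        vox[4, 4, 4] = 5.0
        image = SUVImage(vox, spacing=(1, 1, 1))
        mask, leaked = region_grow(image, (4, 4, 4), 1.0,
                                   ((2, 7), (2, 7), (2, 7)))
        assert not leaked
        assert mask.shape == (1, 3) and tuple(mask[0]) == (4, 4, 4)

    def test_seed_below_threshold_gives_empty(self):
        image = SUVImage(np.ones((5, 5, 5)), spacing=(1, 1, 1))
        mask, leaked = region_grow(image, (2, 2, 2), 2.0,
                                   ((0, 5), (0, 5), (0, 5)))
        assert len(mask) == 0 and not leaked

    def test_uniform_above_threshold_leaks(self):
        image = SUVImage(np.full((12, 12, 12), 3.0), spacing=(1, 1, 1))
        mask, leaked = region_grow(image, (6, 6, 6), 1.0,
                                   ((4, 8), (4, 8), (4, 8)))
        assert leaked

    def test_matches_flood_fill_oracle_on_random_grids(self, rng):
        # exhaustive check on 500 random 6^3 binary grids
        for trial in range(500):
            binary = rng.random((6, 6, 6)) < rng.uniform(0.2, 0.8)
            vox = binary.astype(float) * 2.0
            image = SUVImage(vox, spacing=(1, 1, 1))
            seed = tuple(rng.integers(0, 6, 3))
            mask, _ = region_grow(image, seed, 1.0, ((0, 6), (0, 6), (0, 6)),
                                  leak_margin=0)
            expected = flood_fill_6(binary, seed)
            assert {tuple(v) for v in mask} == expected, f"trial {trial}"

    def test_mask_shrinks_as_threshold_rises(self, rng):
        vox = rng.uniform(0, 10, size=(10, 10, 10))
        seed = tuple(int(i) for i in
                     np.unravel_index(np.argmax(vox), vox.shape))
        image = SUVImage(vox, spacing=(1, 1, 1))
        bounds = ((0, 10), (0, 10), (0, 10))
        sizes = []
        for thr in np.linspace(0.5, 9.5, 12):
            mask, _ = region_grow(image, seed, thr, bounds, leak_margin=0)
            sizes.append(len(mask))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestSegmentLesion:
    def test_blurred_sphere_detected_by_th40(self, hot_sphere_phantom):
        image, annotations, _ = hot_sphere_phantom
        res = segment_lesion(image, annotations[0], ThresholdMethod.TH40,
                             annotations, rng_seed=1)
        assert res.status is SegmentationStatus.DETECTED
        assert res.n_voxels > 0
        assert res.threshold_suv == pytest.approx(0.4 * res.suvmax_lesion)

    def test_sub_threshold_peak_yields_empty(self):
        # peak 2.2 < 2.5: the absolute rule can match no voxel
        spec = PhantomSpec(shape=(40, 40, 40), spacing=(1, 1, 1),
                           background_suv=0.5, noise_sd=0.0, blur_fwhm=0.0,
                           lesions=(LesionSpec(center=(20, 20, 20), radius=6,
                                               peak_suv=2.2),))
        image, annotations, _ = generate_phantom(spec)
        res = segment_lesion(image, annotations[0], ThresholdMethod.TH2_5,
                             annotations)
        assert res.status is SegmentationStatus.EMPTY
        assert res.n_voxels == 0

    def test_hot_background_leaks_absolute_threshold(self):
        # background 3.0 > 2.5 everywhere: the grown region merges with
        # surrounding tissue and must be flagged unsegmentable
        spec = PhantomSpec(shape=(40, 40, 40), spacing=(1, 1, 1),
                           background_suv=3.0, noise_sd=0.0, blur_fwhm=0.0,
                           lesions=(LesionSpec(center=(20, 20, 20), radius=6,
                                               peak_suv=6.0),))
        image, annotations, _ = generate_phantom(spec)
        res = segment_lesion(image, annotations[0], ThresholdMethod.TH2_5,
                             annotations)
        assert res.status is SegmentationStatus.LEAKED

    def test_th40_mask_nested_in_th20(self, hot_sphere_phantom):
        image, annotations, _ = hot_sphere_phantom
        r20 = segment_lesion(image, annotations[0], ThresholdMethod.TH20,
                             annotations)
        r40 = segment_lesion(image, annotations[0], ThresholdMethod.TH40,
                             annotations)
        m20 = {tuple(v) for v in r20.mask}
        m40 = {tuple(v) for v in r40.mask}
        assert m40 <= m20

    def test_detected_mask_voxels_exceed_threshold_and_contain_seed(
            self, hot_sphere_phantom):
        image, annotations, _ = hot_sphere_phantom
        res = segment_lesion(image, annotations[0], ThresholdMethod.THBGD,
                             annotations, rng_seed=4)
        assert res.status is SegmentationStatus.DETECTED
        voxels = image.voxels[res.mask[:, 0], res.mask[:, 1], res.mask[:, 2]]
        assert (voxels > res.threshold_suv).all()
        assert res.seed in {tuple(v) for v in res.mask}
        # background-relative threshold lies between SUVbgd and SUVmax
        assert res.background.suv_bgd <= res.threshold_suv <= res.suvmax_lesion

    def test_annotated_seed_is_respected(self, hot_sphere_phantom):
        image, annotations, _ = hot_sphere_phantom
        ann = annotations[0]
        seeded = LesionAnnotation(ann.lesion_id, ann.site, ann.bbox,
                                  seed=(20, 20, 20))
        res = segment_lesion(image, seeded, ThresholdMethod.TH40, [seeded])
        assert res.seed == (20, 20, 20)
        assert res.suvmax_lesion == pytest.approx(image.voxels[20, 20, 20])
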