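"""Contrast-enhancement detection: filter, masks, thresholds, vessel exclusion."""

import numpy as np
import pytest

from mslesion.enhance import (
    EnhanceParams,
    compute_brain_mask,
    compute_enhance_threshold,
    detect_ce_lesions,
    detect_vessels,
    median_filter3d,
)
from mslesion.io_volumes import BinaryMask, VolumeGrid
from mslesion.phantom import (
    LesionSpec,
    PhantomSpec,
    VesselSpec,
    generate_postcontrast,
)
from tests.conftest import brute_median_filter, make_mask


def vol(data, **kw):
    return VolumeGrid(np.asarray(data, dtype=np.float64), **kw)


class TestMedianFilter:
    def test_constant_unchanged(self):
        v = vol(np.full((5, 5, 5), 7.0))
        np.testing.assert_array_equal(median_filter3d(v).data, v.data)

    def test_single_outlier_removed(self):
        d = np.zeros((5, 5, 5))
        d[2, 2, 2] = 100.0
        assert median_filter3d(vol(d)).data[2, 2, 2] == 0.0

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            median_filter3d(vol(np.zeros((4, 4, 4))), kernel=(2, 3, 3))

    @pytest.mark.parametrize("kernel", [(1, 1, 1), (3, 3, 3), (5, 5, 5), (1, 3, 5)])
    def test_matches_brute_force_oracle(self, kernel):
        rng = np.random.default_rng(8)
        d = rng.random((8, 8, 8))
        got = median_filter3d(vol(d), kernel=kernel).data
        np.testing.assert_allclose(got, brute_median_filter(d, kernel))


class TestBrainMask:
    def test_otsu_two_level(self):
        d = np.zeros((8, 8, 8))
        d[2:6, 2:6, 2:6] = 300.0
        m = compute_brain_mask(vol(d), "otsu")
        np.testing.assert_array_equal(m.as_bool(), d == 300.0)

    def test_fixed_cutoff(self):
        d = np.zeros((4, 4, 4))
        d[0] = 300.0
        m = compute_brain_mask(vol(d), "fixed", fixed_threshold=1.0)
        np.testing.assert_array_equal(m.as_bool(), d == 300.0)

    def test_constant_image_degenerate(self):
        with pytest.raises(ValueError, match="degenerate|constant"):
            compute_brain_mask(vol(np.full((4, 4, 4), 5.0)), "otsu")


class TestThreshold:
    def test_hand_computed_median_mad(self):
        d = np.zeros((3, 3, 3))
        d.flat[:9] = np.arange(1, 10)
        brain = np.zeros((3, 3, 3), dtype=np.uint8)
        brain.flat[:9] = 1
        thr = compute_enhance_threshold(vol(d), make_mask(brain), EnhanceParams(threshold_k=3.0))
        assert thr == pytest.approx(11.0)  # median 5, MAD 2

    def test_constant_region_and_k0(self):
        d = np.full((3, 3, 3), 42.0)
        brain = make_mask(np.ones((3, 3, 3), dtype=np.uint8))
        assert compute_enhance_threshold(vol(d), brain, EnhanceParams(threshold_k=5.0)) == 42.0
        d2 = np.arange(27, dtype=float).reshape(3, 3, 3)
        assert compute_enhance_threshold(vol(d2), brain, EnhanceParams(threshold_k=0.0)) == np.median(d2)

    def test_empty_brain_mask(self):
        brain = make_mask(np.zeros((3, 3, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="empty"):
            compute_enhance_threshold(vol(np.ones((3, 3, 3))), brain, EnhanceParams())


class TestVessels:
    def test_strict_threshold(self):
        d = np.zeros((3, 3, 3))
        d[0, 0, 0], d[1, 1, 1] = 601.0, 600.0
        m = detect_vessels(vol(d))
        assert m.data[0, 0, 0] == 1  # exceeds 600
        assert m.data[1, 1, 1] == 0  # exactly 600 does not exceed
        assert detect_vessels(vol(np.full((3, 3, 3), 599.0))).data.sum() == 0

    def test_phantom_vessels_recovered_exactly(self):
        spec = PhantomSpec(
            seed=1,
            tissue_noise_sd=0.0,
            vessels=[VesselSpec(polyline=[(32, 12, 52), (32, 52, 52)])],
        )
        t1post, vessel_truth, _ = generate_postcontrast(spec, 0)
        np.testing.assert_array_equal(detect_vessels(t1post).data, vessel_truth.data)


def two_lesion_vessel_spec(noise=0.0, seed=1):
    return PhantomSpec(
        seed=seed,
        tissue_noise_sd=noise,
        lesions=[
            LesionSpec(center=(24, 32, 30), enhancing=True),
            LesionSpec(center=(40, 32, 30), enhancing=True),
            LesionSpec(center=(32, 44, 30), enhancing=False),
        ],
        vessels=[VesselSpec(polyline=[(32, 12, 52), (32, 52, 52)])],
    )


class TestDetectCE:
    def test_noiseless_phantom_closed_form(self):
        spec = two_lesion_vessel_spec()
        t1post, vessel_truth, enhancing_truth = generate_postcontrast(spec, 0)
        res = detect_ce_lesions(t1post)
        assert len(res.components) == 2
        assert res.n_excluded_by_vessel == 1  # the vessel is supra-threshold
        assert not np.any(res.candidate_mask.as_bool() & vessel_truth.as_bool())
        # every truth voxel that survives the median filter is recovered
        assert np.all(res.candidate_mask.as_bool() <= enhancing_truth.as_bool())

    def test_no_supra_threshold_voxels(self):
        spec = PhantomSpec(seed=1, tissue_noise_sd=0.0)
        t1post, _, _ = generate_postcontrast(spec, 0)
        assert len(detect_ce_lesions(t1post).components) == 0

    def test_component_overlapping_vessel_excluded(self):
        d = np.full((12, 12, 12), 300.0)
        d[0:2, :, :] = 0.0  # air so otsu has two classes
        d[5:8, 5:8, 5:8] = 500.0  # candidate blob
        # vessel-bright voxel at a face center of the blob, which survives the
        # median filter (a corner voxel would be eroded away)
        d[6, 6, 7] = 650.0
        res = detect_ce_lesions(vol(d))
        assert len(res.components) == 0
        assert res.n_excluded_by_vessel == 1

    def test_restrict_to_lesions(self):
        spec = two_lesion_vessel_spec()
        t1post, _, _ = generate_postcontrast(spec, 0)
        # lesion mask covering only the first enhancing lesion
        from mslesion.phantom import rasterize_ellipsoid

        only_first = rasterize_ellipsoid(spec.shape, spec.spacing, (24, 32, 30), (3, 3, 3))
        res = detect_ce_lesions(t1post, lesion_mask=make_mask(only_first.astype(np.uint8)))
        assert len(res.components) == 1
        assert res.n_excluded_by_lesion_mask == 1

    def test_threshold_monotone_in_k(self):
        """Raising k raises the cutoff and shrinks the supra-threshold set.

        The *component count* itself is not monotone in k (a lower cutoff can
        merge neighboring components into one), so monotonicity is asserted
        on the threshold and on the supra-threshold voxel set.
        """
        spec = two_lesion_vessel_spec(noise=5.0)
        t1post, _, _ = generate_postcontrast(spec, 0)
        filtered = median_filter3d(t1post)
        brain = compute_brain_mask(filtered, "otsu")
        thresholds = [
            compute_enhance_threshold(filtered, brain, EnhanceParams(threshold_k=k))
            for k in (0.5, 2.0, 3.0, 10.0, 100.0)
        ]
        assert thresholds == sorted(thresholds)
        supra_counts = [int(np.sum((filtered.data > t) & brain.as_bool())) for t in thresholds]
        assert supra_counts == sorted(supra_counts, reverse=True)
        assert supra_counts[-1] < supra_counts[0]

    def test_candidate_vessel_disjointness_under_noise(self):
        for seed in range(3):
            spec = two_lesion_vessel_spec(noise=5.0, seed=seed)
            t1post, vessel_truth, enhancing_truth = generate_postcontrast(spec, 0)
            res = detect_ce_lesions(t1post)
            assert not np.any(res.candidate_mask.as_bool() & res.vessel_mask.as_bool())
            assert not np.any(res.candidate_mask.as_bool() & vessel_truth.as_bool())

    def test_grid_mismatch(self):
        from mslesion.io_volumes import GridMismatchError

        spec = two_lesion_vessel_spec()
        t1post, _, _ = generate_postcontrast(spec, 0)
        with pytest.raises(GridMismatchError):
            detect_ce_lesions(t1post, lesion_mask=make_mask(np.zeros((5, 5, 5), np.uint8)))
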