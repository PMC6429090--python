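import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from camvessel.image_io import ROIPolygon
from camvessel.segmentation import (
    SegmentationParams,
    dice_coefficient,
    disk_footprint,
    disk_mean_convolve,
    filter_small_components,
    segment_vessels,
    threshold_vessels,
)
from naive_oracle import naive_disk_mean, naive_segment


class TestDiskMean:
    def test_constant_image_is_fixed_point(self):
        img = np.full((20, 20), 100.0)
        for radius in (1, 3, 7):
            assert np.allclose(disk_mean_convolve(img, radius), 100.0)

    def test_plus_shaped_disk_at_radius_1(self):
        # radius-1 disk is the 5-pixel plus; center mean = 255/5
        img = np.zeros((5, 5))
        img[2, 2] = 255
        assert disk_mean_convolve(img, 1)[2, 2] == pytest.approx(51.0)

    def test_border_means_use_inbounds_subset(self):
        # 1x3 image: border disks have 2 pixels, center has 3
        out = disk_mean_convolve(np.array([[0.0, 255.0, 0.0]]), 1)
        assert out.tolist() == [[127.5, 85.0, 127.5]]

    def test_matches_naive_oracle_on_random_images(self, rng):
        img = rng.integers(0, 256, (32, 32)).astype(float)
        for radius in (1, 2, 5):
            assert np.array_equal(disk_mean_convolve(img, radius), naive_disk_mean(img, radius))

    def test_fft_path_identical_to_direct_path(self, rng):
        # force the FFT path by lowering the size threshold
        import camvessel.segmentation as seg

        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        direct = disk_mean_convolve(img, 5)
        old = seg._FFT_THRESHOLD
        seg._FFT_THRESHOLD = 0
        try:
            fft = disk_mean_convolve(img, 5)
        finally:
            seg._FFT_THRESHOLD = old
        assert np.array_equal(direct, fft)

    def test_rejects_bad_radius(self):
        with pytest.raises(ValueError):
            disk_mean_convolve(np.zeros((4, 4)), 0)

    def test_disk_membership_is_euclidean(self):
        fp = disk_footprint(2)
        # corner offset (2,2) has distance sqrt(8) > 2: excluded
        assert not fp[0, 0]
        # axis offset (0,2) included
        assert fp[2, 4]
        assert fp.sum() == 13


class TestThreshold:
    def test_constant_image_gives_empty_mask(self):
        img = np.full((10, 10), 37.0)
        assert not threshold_vessels(img, img, 1.05).any()

    def test_strict_inequality_boundary(self):
        assert threshold_vessels(np.array([[106.0]]), np.array([[100.0]]), 1.05)[0, 0]
        assert not threshold_vessels(np.array([[105.0]]), np.array([[100.0]]), 1.05)[0, 0]

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            threshold_vessels(np.zeros((3, 3)), np.zeros((3, 4)), 1.05)

    @pytest.mark.parametrize("k", [0.5, 2.0, 4.0])
    def test_gain_invariance_exact_for_power_of_two(self, rng, k):
        img = rng.random((24, 24)) * 200
        conv = disk_mean_convolve(img, 3)
        base = threshold_vessels(conv, img, 1.05)
        scaled = threshold_vessels(disk_mean_convolve(img * k, 3), img * k, 1.05)
        assert np.array_equal(base, scaled)

    def test_gain_invariance_generic_float(self, rng):
        img = rng.random((24, 24)) * 200 + 1
        k = 3.7
        base = threshold_vessels(disk_mean_convolve(img, 3), img, 1.05)
        scaled = threshold_vessels(disk_mean_convolve(img * k, 3), img * k, 1.05)
        assert np.array_equal(base, scaled)


class TestComponentFilter:
    def test_single_pixel_removed(self):
        mask = np.zeros((50, 50), bool)
        mask[10, 10] = True
        assert not filter_small_components(mask, 1000, 4).any()

    def test_size_threshold_is_inclusive(self):
        # components of sizes 100, 999, 1000, 1200; only >= 1000 survive
        mask = np.zeros((120, 300), bool)
        mask[5:15, 5:15] = True  # 100
        mask[5:32, 30:67] = True  # 27*37 = 999
        mask[5:30, 80:120] = True  # 25*40 = 1000
        mask[50:80, 130:170] = True  # 30*40 = 1200
        out = filter_small_components(mask, 1000, 4)
        assert not out[5:15, 5:15].any()
        assert not out[5:32, 30:67].any()
        assert out[5:30, 80:120].all()
        assert out[50:80, 130:170].all()
        assert out.sum() == 2200

    def test_min_size_zero_is_identity(self, rng):
        mask = rng.random((30, 30)) > 0.5
        assert np.array_equal(filter_small_components(mask, 0, 4), mask)

    def test_diagonal_pixels_split_under_4_connectivity(self):
        mask = np.zeros((10, 10), bool)
        mask[2, 2] = mask[3, 3] = True  # one 8-component, two 4-components
        assert not filter_small_components(mask, 2, 4).any()
        assert filter_small_components(mask, 2, 8).sum() == 2

    @given(
        mask=arrays(bool, (16, 16), elements=st.booleans()),
        sizes=st.tuples(st.integers(0, 20), st.integers(0, 20)),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_monotone_in_min_size_and_no_new_pixels(self, mask, sizes):
        lo, hi = min(sizes), max(sizes)
        out_lo = filter_small_components(mask, lo, 4)
        out_hi = filter_small_components(mask, hi, 4)
        assert out_hi.sum() <= out_lo.sum() <= mask.sum()
        assert not (out_lo & ~mask).any()


class TestSegmentVessels:
    def test_constant_image_empty_mask(self):
        img = np.full((64, 64), 120, dtype=np.uint8)
        assert not segment_vessels(img, SegmentationParams(disk_radius=5)).any()

    def test_matches_full_naive_pipeline(self, rng):
        params = SegmentationParams(disk_radius=3, alpha=1.05, min_component_size=15)
        img = rng.integers(0, 256, (48, 48)).astype(np.uint8)
        ours = segment_vessels(img, params)
        oracle = naive_segment(img, 3, 1.05, 15, 4)
        assert np.array_equal(ours, oracle)

    def test_roi_restriction_zeroes_outside(self, rng):
        img = rng.integers(0, 256, (40, 40)).astype(np.uint8)
        roi = ROIPolygon(np.array([(0.0, 0.0), (0.0, 19.0), (39.0, 19.0), (39.0, 0.0)]))
        mask = segment_vessels(img, SegmentationParams(disk_radius=2, min_component_size=0), roi)
        assert not mask[:, 20:].any()

    def test_darkness_selectivity(self, rng):
        # a pixel strictly brighter than all others in its disk is never vessel
        img = rng.integers(0, 200, (30, 30)).astype(float)
        img[15, 15] = 255.0
        mask = segment_vessels(img, SegmentationParams(disk_radius=3, alpha=1.0, min_component_size=0))
        assert not mask[15, 15]

    def test_shape_preserved(self, rng):
        img = rng.integers(0, 256, (21, 33)).astype(np.uint8)
        assert segment_vessels(img, SegmentationParams(disk_radius=2)).shape == (21, 33)

    def test_recovers_thick_dark_vessel_on_phantom(self, small_phantom):
        from camvessel.image_io import extract_green
        from camvessel.synthetic import default_roi

        params, _, image, truth = small_phantom
        roi = default_roi(params).to_mask(params.image_size)
        mask = segment_vessels(extract_green(image), SegmentationParams(), roi)
        assert dice_coefficient(mask & roi, truth & roi) >= 0.8


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"disk_radius": 0},
            {"alpha": 0.0},
            {"min_component_size": -1},
            {"connectivity": 6},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SegmentationParams(**kwargs)
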