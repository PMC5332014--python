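"""Image-processing primitives: filters, thresholding, labeling."""

import numpy as np
import pytest
import scipy.ndimage as ndi

from wpbscreen import (
    CapacityError,
    ParameterError,
    bernsen_threshold,
    label_components,
    median_filter,
    size_filter,
    subtract_background,
    to_8bit,
    watershed_split,
)
from wpbscreen.imgproc import LABEL_CAPACITY

from conftest import bernsen_oracle


class TestMedianFilter:
    def test_constant_image_unchanged(self):
        img = np.full((20, 20), 37, dtype=np.uint16)
        assert np.array_equal(median_filter(img, 2), img)

    def test_impulse_removed(self):
        # a single bright pixel is the window's extreme value everywhere,
        # so the median over a radius-2 disk (13 px) never selects it
        img = np.full((15, 15), 100, dtype=np.uint16)
        img[7, 7] = 4000
        out = median_filter(img, 2)
        assert out[7, 7] == 100
        assert np.array_equal(out, np.full((15, 15), 100))

    def test_second_pass_changes_less(self, rng):
        noisy = rng.integers(0, 4096, (64, 64)).astype(np.uint16)
        once = median_filter(noisy, 2)
        twice = median_filter(once, 2)
        assert (twice != once).sum() < (once != noisy).sum()

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ParameterError):
            median_filter(np.zeros((5, 5)), 0)


class TestSubtractBackground:
    def test_constant_image_becomes_zero(self):
        img = np.full((30, 30), 500, dtype=np.uint16)
        assert np.array_equal(
            subtract_background(img, 1), np.zeros((30, 30), dtype=np.uint16)
        )

    def test_isolated_peak_retained(self):
        # the narrow parabola cannot follow a 1-px spike: the estimated
        # background rises only ~0.5 DN above the plateau under the peak
        img = np.full((31, 31), 200.0)
        img[15, 15] += 100.0
        out = subtract_background(img, 1)
        assert out[15, 15] >= 0.8 * 100.0

    def test_output_nonnegative_and_dtype(self, rng):
        img = rng.integers(0, 4096, (40, 40)).astype(np.uint16)
        out = subtract_background(img, 1)
        assert out.min() >= 0
        assert out.dtype == np.uint16

    def test_gradient_background_flattened(self):
        # a smooth ramp is pure background: rods drawn on top survive
        ramp = np.add.outer(np.arange(40) * 2.0, np.arange(40) * 1.0) + 50
        img = ramp.copy()
        img[20, 10:14] += 800
        out = subtract_background(img.astype(np.uint16), 1)
        assert out[20, 11] > 700
        assert np.median(out) < 5

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ParameterError):
            subtract_background(np.zeros((5, 5)), 0)


class TestBernsen:
    def test_uniform_low_image_is_background(self):
        img = np.full((20, 20), 50, dtype=np.uint8)
        assert not bernsen_threshold(img, 5, 15).any()

    def test_uniform_high_image_is_foreground(self):
        img = np.full((20, 20), 200, dtype=np.uint8)
        assert bernsen_threshold(img, 5, 15).all()

    def test_constructed_window_rule(self):
        # window sees max 200 / min 100 -> contrast 100 >= 15, midgray 150;
        # the 160 center exceeds midgray -> foreground
        img = np.full((5, 5), 100, dtype=np.uint8)
        img[0, 0] = 200
        img[2, 2] = 160
        out = bernsen_threshold(img, 4, 15)
        assert bool(out[2, 2]) is True

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_pixel_oracle(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 256, (32, 32)).astype(np.uint8)
        got = bernsen_threshold(img, 3, 15)
        want = bernsen_oracle(img, 3, 15)
        assert np.array_equal(got, want)

    def test_rejects_out_of_range_contrast(self):
        with pytest.raises(ParameterError):
            bernsen_threshold(np.zeros((5, 5), dtype=np.uint8), 3, 300)

    def test_rejects_non_8bit(self):
        with pytest.raises(ParameterError):
            bernsen_threshold(np.full((5, 5), 4000), 3, 15)


class TestTo8Bit:
    def test_linear_mapping_endpoints(self):
        img = np.array([[0, 4095], [2048, 4095]], dtype=np.uint16)
        out = to_8bit(img)
        assert out[0, 0] == 0 and out[0, 1] == 255
        assert out[1, 0] == 128  # round(2048 * 255 / 4095)


class TestWatershedSplit:
    @staticmethod
    def _disk_mask(shape, centers, radius):
        mask = np.zeros(shape, dtype=bool)
        rr, cc = np.mgrid[: shape[0], : shape[1]]
        for r, c in centers:
            mask |= (rr - r) ** 2 + (cc - c) ** 2 <= radius**2
        return mask

    def test_single_disk_unchanged(self):
        mask = self._disk_mask((40, 40), [(20, 20)], 10)
        out = watershed_split(mask)
        assert np.array_equal(out, mask)

    def test_two_overlapping_disks_split(self):
        # centers 1.7 radii apart: a clear two-lobed blob
        mask = self._disk_mask((60, 80), [(30, 30), (30, 47)], 10)
        assert ndi.label(mask, structure=np.ones((3, 3)))[1] == 1
        out = watershed_split(mask)
        assert ndi.label(out, structure=np.ones((3, 3)))[1] == 2

    def test_empty_mask(self):
        empty = np.zeros((10, 10), dtype=bool)
        assert not watershed_split(empty).any()


class TestLabelComponents:
    def test_two_blobs_get_raster_order_labels(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[1:3, 1:3] = True
        mask[6:9, 6:9] = True
        lab = label_components(mask)
        assert set(np.unique(lab)) == {0, 1, 2}
        assert lab[1, 1] == 1 and lab[7, 7] == 2

    def test_empty_mask(self):
        lab = label_components(np.zeros((5, 5), dtype=bool))
        assert lab.max() == 0

    def test_diagonal_pixels_are_one_component(self):
        mask = np.zeros((6, 6), dtype=bool)
        mask[1, 1] = mask[2, 2] = mask[3, 3] = True
        lab = label_components(mask)
        # flood-fill oracle with 8-connectivity
        want, n = ndi.label(mask, structure=np.ones((3, 3)))
        assert n == 1 and lab.max() == 1
        assert np.array_equal(lab > 0, want > 0)

    def test_capacity_error_at_8bit_limit(self):
        # 16x16 grid of isolated pixels = 256 objects > the 255 labels an
        # 8-bit raster can hold beside the reserved 0
        mask = np.zeros((32, 32), dtype=bool)
        mask[::2, ::2] = True
        assert mask.sum() == 256
        with pytest.raises(CapacityError):
            label_components(mask, capacity=LABEL_CAPACITY[8])
        lab = label_components(mask, capacity=LABEL_CAPACITY[16])
        assert lab.max() == 256


class TestSizeFilter:
    def test_direct_bounds(self):
        # areas 30 / 100 / 3000 um^2 at 1 um/px against bounds [50, 2500]
        lab = np.zeros((100, 100), dtype=int)
        lab[0:5, 0:6] = 1      # 30
        lab[10:20, 10:20] = 2  # 100
        lab[40:90, 40:100] = 3 # 3000
        out = size_filter(lab, 50, 2500, 1.0)
        assert set(np.unique(out)) == {0, 2}

    def test_clump_bound_removes_12um2(self):
        lab = np.zeros((10, 10), dtype=int)
        lab[2:5, 2:6] = 1  # 12 px = 12 um^2 at 1 um/px
        out = size_filter(lab, None, 10.0, 1.0)
        assert out.max() == 0

    def test_no_bounds_is_identity(self, rng):
        lab = (rng.random((30, 30)) < 0.3).astype(int)
        lab = label_components(lab > 0)
        assert np.array_equal(size_filter(lab, None, None, 0.5), lab)

    def test_idempotent(self, rng):
        lab = label_components(rng.random((50, 50)) < 0.25)
        once = size_filter(lab, 2.0, 40.0, 1.0)
        assert np.array_equal(size_filter(once, 2.0, 40.0, 1.0), once)

    def test_rejects_inverted_bounds(self):
        with pytest.raises(ParameterError):
            size_filter(np.zeros((5, 5), dtype=int), 10, 5, 1.0)
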