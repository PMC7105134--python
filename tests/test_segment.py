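"""Unit tests for the threshold algorithms, SUVpeak and the gradient image."""

import numpy as np
import pytest

from petseg import (
    AutoParams,
    BinaryMask,
    SUVImage,
    auto_segment,
    gradient_image,
    keep_largest_component,
    sphere_diameter_cm,
    suv_peak,
    threshold_fixed,
    threshold_pct_max,
)
from petseg.segment import PANEL_LABELS, ThresholdRule, _sphere_kernel, run_auto_panel


def _full_mask(image):
    return BinaryMask(values=np.ones(image.shape, bool), spacing=image.spacing)


class TestThresholds:
    def test_pct_max_strictly_greater(self):
        v = np.zeros((3, 3, 3))
        v[1, 1, 1] = 10.0
        v[0, 0, 0] = 4.1
        v[0, 0, 1] = 4.0
        img = SUVImage(values=v, spacing=(4, 4, 4))
        res = threshold_pct_max(img, _full_mask(img), 40.0)
        assert res.mask.values[1, 1, 1] and res.mask.values[0, 0, 0]
        assert not res.mask.values[0, 0, 1]  # exactly at the cut -> excluded
        assert res.threshold_suv == pytest.approx(4.0)
        assert res.rule is ThresholdRule.PCT_MAX

    def test_pct_100_is_empty(self, small_case):
        res = threshold_pct_max(small_case.image, small_case.rough_mask, 100.0)
        assert not res.mask.values.any()

    def test_pct_0_fills_positive_part(self):
        v = np.full((3, 3, 3), 2.0)
        img = SUVImage(values=v, spacing=(4, 4, 4))
        res = threshold_pct_max(img, _full_mask(img), 0.0)
        assert res.mask.values.all()

    def test_nesting_in_pct(self, small_case):
        prev = None
        for pct in range(0, 101, 10):
            cur = threshold_pct_max(small_case.image, small_case.rough_mask, pct).mask.values
            if prev is not None:
                assert np.all(prev[cur])  # higher pct selects a subset
            prev = cur

    def test_fixed_nesting_and_strictness(self, small_case):
        lo = threshold_fixed(small_case.image, small_case.rough_mask, 2.5).mask.values
        hi = threshold_fixed(small_case.image, small_case.rough_mask, 4.0).mask.values
        assert np.all(lo[hi])

    def test_respects_rough_mask(self, small_case):
        res = threshold_fixed(small_case.image, small_case.rough_mask, 0.0)
        assert not np.any(res.mask.values & ~small_case.rough_mask.values)

    def test_input_validation(self, small_case):
        with pytest.raises(ValueError):
            threshold_pct_max(small_case.image, small_case.rough_mask, 101.0)
        with pytest.raises(ValueError):
            threshold_fixed(small_case.image, small_case.rough_mask, -1.0)
        empty = BinaryMask(
            values=np.zeros(small_case.image.shape, bool), spacing=small_case.image.spacing
        )
        with pytest.raises(ValueError, match="empty"):
            threshold_pct_max(small_case.image, empty, 41.0)


class TestSUVPeak:
    def test_kernel_19_voxels_on_4mm_grid(self):
        # within 6 mm of a center on a 4 mm grid: self, 6 faces (4 mm),
        # 12 edges (5.66 mm); 8 corners (6.93 mm) are outside
        k = _sphere_kernel((4.0, 4.0, 4.0), 6.0)
        assert k.sum() == 19

    def test_uniform_image(self):
        img = SUVImage(values=np.full((7, 7, 7), 3.0), spacing=(4, 4, 4))
        peak, _ = suv_peak(img, _full_mask(img))
        assert peak == pytest.approx(3.0)

    def test_hot_voxel_is_averaged_down(self):
        v = np.ones((9, 9, 9))
        v[4, 4, 4] = 20.0
        img = SUVImage(values=v, spacing=(4, 4, 4))
        peak, idx = suv_peak(img, _full_mask(img))
        # the best neighborhood is any one containing the hot voxel
        assert peak == pytest.approx((20.0 + 18.0) / 19.0)
        assert np.linalg.norm((np.asarray(idx) - 4) * 4.0) <= 6.0

    def test_brute_force_small(self):
        rng = np.random.default_rng(9)
        img = SUVImage(values=rng.random((6, 6, 6)) * 10, spacing=(3.0, 3.0, 2.0))
        mask = BinaryMask(values=rng.random((6, 6, 6)) < 0.5, spacing=(3.0, 3.0, 2.0))
        peak, idx = suv_peak(img, mask)
        # independent oracle: explicit mm-distance neighborhoods
        coords = np.stack(
            np.meshgrid(*[np.arange(n) * s for n, s in zip(img.shape, img.spacing)], indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)
        vals = img.values.reshape(-1)
        best = -np.inf
        for p in np.argwhere(mask.values):
            c = np.asarray(p) * img.spacing
            sel = ((coords - c) ** 2).sum(1) <= 36.0 + 1e-9
            best = max(best, vals[sel].mean())
        assert peak == pytest.approx(best, rel=1e-12)


class TestAuto:
    def test_recovers_analytic_fixed_point(self, clean_case):
        # background 1, peak 8 -> T = 1 + 0.5*(8-1) = 4.5, VOI = ground truth
        res = auto_segment(clean_case.image, clean_case.rough_mask)
        assert res.converged
        assert res.threshold_suv == pytest.approx(4.5, abs=1e-3)
        np.testing.assert_array_equal(res.mask.values, clean_case.ground_truth.values)

    def test_converges_on_noisy_case(self, small_case):
        res = auto_segment(small_case.image, small_case.rough_mask)
        assert res.converged
        assert res.mask.values.any()

    def test_params_validation(self):
        with pytest.raises(ValueError):
            AutoParams(peak_fraction=1.5)
        with pytest.raises(ValueError):
            AutoParams(shell_inner_mm=10.0, shell_outer_mm=2.0)
        with pytest.raises(ValueError):
            AutoParams(damping=0.0)

    def test_panel_labels_and_order(self, small_case):
        panel = run_auto_panel(small_case.image, small_case.rough_mask)
        assert tuple(panel) == PANEL_LABELS
        assert panel["SUV4"].threshold_suv == 4.0
        assert panel["SUV2.5"].threshold_suv == 2.5
        # SUV2.5 mask contains SUV4 mask (nesting of fixed cuts)
        assert np.all(panel["SUV2.5"].mask.values[panel["SUV4"].mask.values])


class TestGradient:
    def test_linear_ramp_slope(self):
        for spacing in [(4.0, 4.0, 4.0), (3.1819, 3.1819, 2.0)]:
            x = np.arange(24) * spacing[0]
            v = np.broadcast_to(0.5 * x[:, None, None], (24, 24, 24)).copy()
            img = SUVImage(values=v, spacing=spacing)
            g = gradient_image(img)
            interior = g.values[8:16, 8:16, 8:16]
            # the truncated discrete Gaussian derivative is exact to ~1e-4
            np.testing.assert_allclose(interior, 0.5, rtol=1e-3)

    def test_uniform_image_zero_gradient(self):
        img = SUVImage(values=np.full((10, 10, 10), 2.0), spacing=(4, 4, 4))
        g = gradient_image(img)
        np.testing.assert_allclose(g.values, 0.0, atol=1e-12)

    def test_peak_at_edge(self, clean_case):
        g = gradient_image(clean_case.image)
        # the gradient maximum sits near the tumor boundary, not deep inside
        idx = np.unravel_index(np.argmax(g.values), g.values.shape)
        from scipy import ndimage

        boundary = clean_case.ground_truth.values ^ ndimage.binary_erosion(
            clean_case.ground_truth.values, iterations=2
        )
        near_boundary = ndimage.binary_dilation(boundary, iterations=2)
        assert near_boundary[idx]


class TestMisc:
    def test_keep_largest_component(self):
        v = np.zeros((10, 10, 10), bool)
        v[1:5, 1:5, 1:5] = True
        v[8, 8, 8] = True
        out = keep_largest_component(BinaryMask(values=v, spacing=(1, 1, 1)))
        assert out.n_voxels == 64 and not out.values[8, 8, 8]

    def test_sphere_diameter_analytic(self):
        assert sphere_diameter_cm(1.0) == pytest.approx(1.2407, abs=5e-4)
        assert sphere_diameter_cm(4.0 / 3.0 * np.pi) == pytest.approx(2.0, rel=1e-12)
        with pytest.raises(ValueError):
            sphere_diameter_cm(0.0)
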