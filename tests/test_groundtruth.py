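"""Density-map and attention-map ground truth construction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.signal import convolve2d

from earcount.annotation_io import PointAnnotationSet
from earcount.groundtruth import (count_from_density, default_radius,
                                  gaussian_kernel, make_attention_map,
                                  make_density_map, pool_to_stride,
                                  smooth_density)


class TestGaussianKernel:
    def test_unit_sum_and_symmetry(self):
        k = gaussian_kernel(sigma=2.5, radius=7)
        assert abs(k.weights.sum() - 1.0) < 1e-9
        assert np.abs(k.weights - k.weights[::-1, :]).max() < 1e-9
        assert np.abs(k.weights - k.weights[:, ::-1]).max() < 1e-9
        assert np.abs(k.weights - k.weights.T).max() < 1e-9

    def test_centre_dominates(self):
        k = gaussian_kernel(sigma=1.0, radius=1)
        assert (k.weights[1, 1] > k.weights).sum() == 8

    def test_centre_weight_matches_direct_formula(self):
        sigma, radius = 1.0, 4
        k = gaussian_kernel(sigma, radius)
        ax = np.arange(-radius, radius + 1)
        raw = np.exp(-(ax[:, None] ** 2 + ax[None, :] ** 2) / (2 * sigma ** 2))
        assert abs(k.weights[radius, radius] - raw[radius, radius] / raw.sum()) < 1e-9

    @pytest.mark.parametrize("sigma,radius", [(0.0, 3), (-1.0, 3), (2.0, 0)])
    def test_invalid_parameters_rejected(self, sigma, radius):
        with pytest.raises(ValueError):
            gaussian_kernel(sigma, radius)


class TestDensityMap:
    def test_no_points_gives_zero_map(self):
        d = make_density_map(np.empty((0, 2)), (32, 32), sigma=2)
        assert d.shape == (32, 32) and d.sum() == 0.0

    def test_single_centred_point_sums_to_one(self):
        d = make_density_map(np.array([[16.0, 16.0]]), (33, 33), sigma=4)
        assert abs(d.sum() - 1.0) < 1e-6
        assert d.min() >= 0

    def test_coincident_corner_points_renormalised(self):
        # brute-force oracle: stamp the kernel at (0,0), keep the in-grid
        # quadrant, renormalise, double it
        sigma = 3.0
        r = default_radius(sigma)
        k = gaussian_kernel(sigma, r).weights
        patch = k[r:, r:]
        expected = 2.0 * patch / patch.sum()
        d = make_density_map(np.array([[0.0, 0.0], [0.0, 0.0]]), (64, 64),
                             sigma=sigma)
        assert abs(d.sum() - 2.0) < 1e-6
        assert np.abs(d[:r + 1, :r + 1] - expected).max() < 1e-12

    def test_count_conserved_for_border_points(self, rng):
        h, w = 57, 83
        pts = np.column_stack([rng.uniform(0, w, 150), rng.uniform(0, h, 150)])
        pts[:5] = [[0, 0], [w - 1e-9, 0], [0, h - 1e-9],
                   [w - 1e-9, h - 1e-9], [w / 2, 0]]
        d = make_density_map(pts, (h, w), sigma=8)
        assert abs(d.sum() - 150) < 1e-6 * 150

    def test_superposition(self, rng):
        h, w = 40, 40
        p1 = rng.uniform(0, 39, size=(7, 2))
        p2 = rng.uniform(0, 39, size=(5, 2))
        d12 = make_density_map(np.vstack([p1, p2]), (h, w), sigma=2)
        d1 = make_density_map(p1, (h, w), sigma=2)
        d2 = make_density_map(p2, (h, w), sigma=2)
        assert np.abs(d12 - (d1 + d2)).max() < 1e-12

    def test_point_outside_domain_raises(self):
        with pytest.raises(ValueError, match="outside"):
            make_density_map(np.array([[40.0, 10.0]]), (32, 32), sigma=2)

    def test_accepts_point_annotation_set(self):
        ann = PointAnnotationSet("img", (32, 32), [(10, 10), (20, 20)])
        d = make_density_map(ann, (32, 32), sigma=2)
        assert abs(d.sum() - 2.0) < 1e-6

    def test_flip_equivariance(self, rng):
        h, w = 48, 64
        pts = np.column_stack([rng.uniform(0, w, 50), rng.uniform(0, h, 50)])
        flipped = pts.copy()
        flipped[:, 0] = np.clip((w - 1) - flipped[:, 0], 0, w - 1e-9)
        d = make_density_map(pts, (h, w), sigma=3)
        df = make_density_map(flipped, (h, w), sigma=3)
        assert np.abs(df - d[:, ::-1]).max() < 1e-9


class TestAttentionMap:
    def test_zero_density_gives_zero_attention(self):
        a = make_attention_map(np.zeros((32, 32)), sigma=4, th=1e-3)
        assert a.shape == (32, 32) and not a.any()

    def test_threshold_is_inclusive(self):
        d = make_density_map(np.array([[16.0, 16.0]]), (33, 33), sigma=4)
        z = smooth_density(d, sigma=4)
        th = float(z[10, 16])  # an exactly attained smoothed value
        a = make_attention_map(d, sigma=4, th=th)
        assert a[10, 16] == 1.0

    def test_active_set_matches_direct_convolution(self):
        sigma, th = 4.0, 1e-3
        d = make_density_map(np.array([[20.0, 24.0]]), (48, 48), sigma=sigma)
        r = default_radius(sigma)
        k = gaussian_kernel(sigma, r).weights
        z_direct = convolve2d(d, k, mode="same", boundary="fill")
        a = make_attention_map(d, sigma=sigma, th=th)
        assert np.array_equal(a.astype(bool), z_direct >= th)

    def test_values_are_binary(self, rng):
        d = make_density_map(rng.uniform(0, 31, size=(20, 2)), (32, 32), sigma=2)
        a = make_attention_map(d, sigma=2)
        assert set(np.unique(a)) <= {0.0, 1.0}

    @given(th_lo=st.floats(1e-5, 1e-2), factor=st.floats(1.0, 10.0))
    def test_raising_threshold_never_adds_pixels(self, th_lo, factor):
        d = make_density_map(np.array([[16.0, 16.0], [5.0, 25.0]]), (33, 33),
                             sigma=3)
        lo = make_attention_map(d, sigma=3, th=th_lo)
        hi = make_attention_map(d, sigma=3, th=th_lo * factor)
        assert not np.any(hi > lo)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            make_attention_map(np.zeros((8, 8)), sigma=2, th=0.0)


class TestCounting:
    def test_count_is_map_integral(self, rng):
        d = make_density_map(rng.uniform(0, 63, size=(7, 2)), (64, 64), sigma=4)
        assert abs(count_from_density(d) - 7.0) < 1e-5
        assert count_from_density(np.zeros((4, 4))) == 0.0
        assert abs(count_from_density(2 * d) - 2 * count_from_density(d)) < 1e-9

    def test_pool_to_stride_conserves_mass(self, rng):
        d = make_density_map(rng.uniform(0, 63, size=(9, 2)), (64, 64), sigma=4)
        pooled = pool_to_stride(d, 4)
        assert pooled.shape == (16, 16)
        assert abs(pooled.sum() - d.sum()) < 1e-9
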