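"""The composite counting objective: Euclidean density loss, SSIM local
consistency, attention cross-entropy, and their weighted combination."""

import numpy as np
import pytest

from earcount.groundtruth import make_attention_map, make_density_map
from earcount.losses import (LossBreakdown, SSIMConfig, attention_loss,
                             combined_loss, consistency_loss, density_loss,
                             ssim_index, ssim_map, total_loss)
from earcount.network.autograd import Tensor


class TestDensityLoss:
    def test_zero_when_identical(self, rng):
        x = rng.random((16, 16))
        assert density_loss(x, x) == 0.0

    def test_constant_offset_closed_form(self, rng):
        x = rng.random((16, 16))
        c = 0.37
        assert abs(density_loss(x + c, x) - c ** 2) < 1e-12

    def test_symmetry(self, rng):
        x, y = rng.random((8, 8)), rng.random((8, 8))
        assert density_loss(x, y) == density_loss(y, x)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            density_loss(rng.random((4, 4)), rng.random((5, 5)))


class TestSSIM:
    def test_self_similarity_is_one(self, rng):
        for _ in range(5):
            x = rng.random((24, 24))
            assert abs(ssim_index(x, x) - 1.0) < 1e-12

    def test_symmetry(self, rng):
        x, y = rng.random((24, 24)), rng.random((24, 24))
        assert abs(ssim_index(x, y) - ssim_index(y, x)) < 1e-12

    def test_range(self, rng):
        for _ in range(10):
            v = ssim_index(rng.random((16, 16)), rng.random((16, 16)))
            assert -1.0 - 1e-9 <= v <= 1.0 + 1e-9

    def test_full_grid_uniform_window_matches_single_window_formula(self, rng):
        """With a uniform window exactly covering the grid, the SSIM value at
        the centre pixel equals the one-window closed form with the
        1/(M-1) variance/covariance estimator."""
        r = 4
        n = 2 * r + 1
        cfg = SSIMConfig(window_radius=r, window="uniform")
        x = rng.random((n, n))
        y = rng.random((n, n))
        m = n * n
        mu_x, mu_y = x.mean(), y.mean()
        var_x = ((x - mu_x) ** 2).sum() / (m - 1)
        var_y = ((y - mu_y) ** 2).sum() / (m - 1)
        cov = ((x - mu_x) * (y - mu_y)).sum() / (m - 1)
        expected = ((2 * mu_x * mu_y + cfg.c1) * (2 * cov + cfg.c2) /
                    ((mu_x ** 2 + mu_y ** 2 + cfg.c1) * (var_x + var_y + cfg.c2)))
        got = ssim_map(x, y, cfg)[0, 0, r, r]
        assert abs(got - expected) < 1e-9


class TestConsistencyLoss:
    def test_zero_for_identical_maps(self, rng):
        x = rng.random((16, 16))
        assert abs(consistency_loss(x, x)) < 1e-12

    def test_bounded_zero_two(self, rng):
        for _ in range(10):
            v = consistency_loss(rng.random((12, 12)), rng.random((12, 12)))
            assert -1e-9 <= v <= 2.0 + 1e-9

    def test_sign_flipped_map_exceeds_one(self, rng):
        # a zero-mean pattern against its negation: the mean terms vanish,
        # the covariance flips sign, and SSIM goes negative; evaluated at
        # the pixel whose window covers the whole (zero-mean) grid
        r = 4
        cfg = SSIMConfig(window_radius=r, window="uniform")
        x = rng.standard_normal((2 * r + 1, 2 * r + 1))
        x -= x.mean()
        assert 1.0 - ssim_map(x, -x, cfg)[0, 0, r, r] > 1.0


class TestAttentionLoss:
    def test_uniform_half_probability_gives_log_two(self, rng):
        gt = (rng.random((16, 16)) > 0.5).astype(float)
        p = np.full((16, 16), 0.5)
        assert abs(attention_loss(p, gt) - np.log(2.0)) < 1e-9

    def test_confident_correct_closed_form(self):
        gt = np.ones((8, 8))
        p = np.full((8, 8), 0.9)
        assert abs(attention_loss(p, gt) + np.log(0.9)) < 1e-9

    def test_loss_decreases_as_prediction_approaches_truth(self, rng):
        gt = (rng.random((16, 16)) > 0.5).astype(float)
        losses = [attention_loss(np.clip(gt, 1 - q, q), gt)
                  for q in (0.6, 0.8, 0.95, 0.999)]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_non_binary_ground_truth_rejected(self, rng):
        with pytest.raises(ValueError):
            attention_loss(np.full((4, 4), 0.5), np.full((4, 4), 0.3))


class TestTotalLoss:
    def test_weighted_sum_identity(self):
        bd = total_loss(0.5, 0.2, 1.0, alpha=0.1)
        assert abs(bd.total - 0.8) < 1e-12
        assert total_loss(0.0, 0.0, 0.0, alpha=0.7).total == 0.0

    def test_alpha_zero_ignores_attention(self):
        assert total_loss(0.3, 0.1, 5.0, alpha=0.0).total == pytest.approx(0.4)

    def test_negative_component_rejected(self):
        with pytest.raises(ValueError):
            total_loss(-0.1, 0.0, 0.0)

    def test_breakdown_identity_random(self, rng):
        for _ in range(20):
            a, b, c = rng.random(3)
            alpha = rng.random()
            bd = total_loss(a, b, c, alpha)
            assert abs(bd.total - (a + b + c * alpha)) < 1e-9


class TestGradients:
    def test_all_components_have_finite_gradients(self, rng):
        pts = rng.uniform(0, 31, size=(6, 2))
        gt_d = make_density_map(pts, (32, 32), sigma=2)
        gt_a = make_attention_map(gt_d, sigma=2)
        pred_d = Tensor(rng.random((1, 1, 32, 32)), requires_grad=True)
        pred_a = Tensor(rng.uniform(0.01, 0.99, (1, 1, 32, 32)),
                        requires_grad=True)
        loss, bd = combined_loss(pred_d, pred_a, gt_d[None, None],
                                 gt_a[None, None], alpha=0.1)
        loss.backward()
        assert np.isfinite(loss.item())
        assert np.isfinite(pred_d.grad).all()
        assert np.isfinite(pred_a.grad).all()
        assert isinstance(bd, LossBreakdown)
        assert abs(bd.total - (bd.l_den + bd.l_c + bd.alpha * bd.l_att)) < 1e-9
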