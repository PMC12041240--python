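"""Composite objective: BerHu branches, MS-SSIM against an independent
windowed-statistics oracle, the adversarial terms, and unit normalization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import correlate

from lfrecon.losses import (LossConfig, adversarial_losses, berhu,
                            combine_losses, msssim, msssim_loss,
                            normalize_unit, total_generator_loss)
from lfrecon.nn.autograd import Tensor


class TestBerhu:
    def test_l1_branch(self):
        assert berhu(np.array([0.05]), np.array([0.0]), 0.1) == pytest.approx(0.05)

    def test_quadratic_branch(self):
        # (0.3² + 0.1²)/(2·0.1) = 0.5
        assert berhu(np.array([0.3]), np.array([0.0]), 0.1) == pytest.approx(0.5)

    def test_branches_continuous_at_threshold(self):
        below = berhu(np.array([0.1 - 1e-9]), np.array([0.0]), 0.1)
        above = berhu(np.array([0.1 + 1e-9]), np.array([0.0]), 0.1)
        assert below == pytest.approx(0.1, abs=1e-8)
        assert above == pytest.approx(0.1, abs=1e-8)

    def test_identity_and_sign_symmetry(self, rng):
        x = rng.random((8, 8))
        assert berhu(x, x, 0.1) == 0.0
        d = rng.standard_normal((8, 8))
        assert berhu(x + d, x, 0.1) == pytest.approx(berhu(x - d, x, 0.1))

    def test_nonnegative(self, rng):
        for _ in range(5):
            a, b = rng.standard_normal((4, 4)), rng.standard_normal((4, 4))
            assert berhu(a, b, 0.1) >= 0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            berhu(np.zeros((2, 2)), np.zeros((3, 3)), 0.1)


def _msssim_oracle(x, y, cfg: LossConfig):
    """Direct per-scale Gaussian-window evaluation (scipy correlate path,
    independent of the autodiff implementation)."""
    ax = np.arange(cfg.msssim_window) - (cfg.msssim_window - 1) / 2
    g1 = np.exp(-(ax ** 2) / (2 * cfg.msssim_sigma ** 2))
    w2 = np.outer(g1, g1)
    w2 /= w2.sum()
    weights = np.array(cfg.msssim_weights[: cfg.msssim_levels])
    weights = weights / weights.sum()

    def stats(a, b):
        interior = (slice(cfg.msssim_window // 2, -(cfg.msssim_window // 2)),) * 2
        mua = correlate(a, w2)[interior]
        mub = correlate(b, w2)[interior]
        va = np.maximum(correlate(a * a, w2)[interior] - mua ** 2, 0)
        vb = np.maximum(correlate(b * b, w2)[interior] - mub ** 2, 0)
        cab = correlate(a * b, w2)[interior] - mua * mub
        return mua, mub, va, vb, cab

    total = 1.0
    for j in range(cfg.msssim_levels):
        mua, mub, va, vb, cab = stats(x, y)
        sa, sb = np.sqrt(va), np.sqrt(vb)
        contrast = ((2 * sa * sb + cfg.c2) / (va + vb + cfg.c2)).mean()
        structure = ((cab + cfg.c3) / (sa * sb + cfg.c3)).mean()
        total *= max(contrast, 1e-7) ** weights[j] * \
            max(structure, 1e-7) ** weights[j]
        if j == cfg.msssim_levels - 1:
            lum = ((2 * mua * mub + cfg.c1)
                   / (mua ** 2 + mub ** 2 + cfg.c1)).mean()
            total *= max(lum, 1e-7) ** weights[j]
        else:
            h, w = x.shape
            x = x[: h // 2 * 2, : w // 2 * 2].reshape(h // 2, 2, w // 2, 2).mean((1, 3))
            y = y[: h // 2 * 2, : w // 2 * 2].reshape(h // 2, 2, w // 2, 2).mean((1, 3))
    return total


class TestMsssim:
    cfg = LossConfig(msssim_levels=2)

    def test_identical_images_score_one(self, rng):
        x = rng.random((64, 64))
        assert msssim(x, x, self.cfg) == pytest.approx(1.0, abs=1e-9)
        assert msssim_loss(x, x, self.cfg) == pytest.approx(0.0, abs=1e-9)

    def test_noise_vs_structure_below_one(self, rng):
        yy, xx = np.mgrid[0:64, 0:64]
        target = np.sin(xx / 5.0) * np.cos(yy / 7.0) * 0.5 + 0.5
        noise = rng.random((64, 64))
        assert msssim(noise, target, self.cfg) < 0.5

    def test_matches_independent_oracle(self, rng):
        cfg = LossConfig(msssim_levels=3)
        for _ in range(20):
            x = rng.random((96, 96))
            y = np.clip(x + 0.2 * rng.standard_normal((96, 96)), 0, 1)
            mine = msssim(x, y, cfg)
            oracle = _msssim_oracle(x, y, cfg)
            assert mine == pytest.approx(oracle, abs=1e-6)

    def test_symmetric(self, rng):
        x, y = rng.random((64, 64)), rng.random((64, 64))
        assert msssim(x, y, self.cfg) == pytest.approx(
            msssim(y, x, self.cfg), abs=1e-12)

    def test_bounded_on_nonnegative_inputs(self, rng):
        for _ in range(5):
            x, y = rng.random((48, 48)), rng.random((48, 48))
            v = msssim(x, y, LossConfig(msssim_levels=1))
            assert 0.0 <= v <= 1.0

    def test_too_small_image_suggests_fewer_levels(self):
        with pytest.raises(ValueError, match="msssim_levels"):
            msssim(np.zeros((32, 32)), np.zeros((32, 32)),
                   LossConfig(msssim_levels=5))


class TestAdversarial:
    def test_balanced_scores(self):
        d_obj, g_bce = adversarial_losses(0.5, 0.5)
        assert d_obj == pytest.approx(np.log(0.5))
        assert g_bce == pytest.approx(-np.log(0.5))

    def test_perfect_discriminator_reaches_supremum(self):
        d_obj, _ = adversarial_losses(1.0 - 1e-9, 1e-9)
        assert d_obj == pytest.approx(0.0, abs=1e-6)

    def test_generator_optimum(self):
        _, g_bce = adversarial_losses(0.5, 1.0 - 1e-9)
        assert g_bce == pytest.approx(0.0, abs=1e-6)

    def test_extreme_scores_clamped_finite(self):
        d_obj, g_bce = adversarial_losses(0.0, 1.0)
        assert np.isfinite(d_obj) and np.isfinite(g_bce)


class TestTotalLoss:
    def test_unit_components_weighted_sum(self):
        assert combine_losses(1.0, 1.0, 1.0, LossConfig()) == pytest.approx(4.5)

    def test_zero_weights_zero_loss(self, rng):
        cfg = LossConfig(alpha=0, beta=0, gamma=0)
        assert combine_losses(3.3, 1.2, 9.9, cfg) == 0.0

    def test_identical_pred_reduces_to_adversarial_term(self, rng):
        x = rng.random((48, 48))
        cfg = LossConfig(msssim_levels=1, gamma=0.5)
        total = total_generator_loss(x, x, 0.5, cfg)
        assert total == pytest.approx(0.5 * (-np.log(0.5)), abs=1e-9)

    def test_decreases_under_gradient_steps_on_toy_generator(self, rng):
        # one-parameter generator: pred = w * target
        target = rng.random((48, 48)) + 0.1
        cfg = LossConfig(msssim_levels=1, berhu_reduction="mean", gamma=0.0)
        w = Tensor(np.array(0.2), requires_grad=True)
        losses = []
        for _ in range(100):
            pred = w * Tensor(target)
            loss = (cfg.alpha * berhu(pred, Tensor(target), cfg.berhu_c,
                                      reduction="mean")
                    + cfg.beta * (1.0 - msssim(pred, Tensor(target), cfg)))
            w.zero_grad()
            loss.backward()
            w.data -= 0.02 * w.grad
            losses.append(loss.item())
        assert losses[-1] < losses[0]
        assert w.item() == pytest.approx(1.0, abs=0.05)


class TestNormalize:
    def test_three_point_example(self):
        np.testing.assert_allclose(normalize_unit(np.array([2.0, 3.0, 4.0])),
                                   [-1.0, 0.0, 1.0])

    def test_exact_range_endpoints(self, rng):
        x = rng.standard_normal((32, 32))
        out = normalize_unit(x)
        assert out.min() == -1.0 and out.max() == 1.0

    @settings(deadline=None, max_examples=25)
    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5), seed=st.integers(0, 999))
    def test_positive_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        np.testing.assert_allclose(normalize_unit(a * x + b),
                                   normalize_unit(x), atol=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_unit(np.ones(10))
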