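import math

import numpy as np
import pytest

from slabrestore.losses import (
    LossWeights, charbonnier, combined_loss, nig_loss, ssim_loss, ssim_per_image,
)
from slabrestore.nn import Tensor


def nig_scalar_oracle(y, g, v, a, b, lam):
    """Independent pointwise evaluation of the evidential loss via math.*."""
    om = 2.0 * b * (1.0 + v)
    nll = (0.5 * math.log(math.pi / v) - a * math.log(om)
           + (a + 0.5) * math.log((y - g) ** 2 * v + om)
           + math.lgamma(a) - math.lgamma(a + 0.5))
    return nll + lam * abs(y - g) * (2.0 * v + a)


class TestCharbonnier:
    def test_identical_images_equal_sqrt_eps(self, rng):
        img = rng.random((2, 1, 8, 8))
        assert charbonnier(img, img).item() == pytest.approx(1e-2, rel=1e-12)

    def test_single_voxel_value(self):
        assert charbonnier(np.array([[0.1]]), np.array([[0.0]])).item() == pytest.approx(
            math.sqrt(0.01 + 1e-4), rel=1e-12
        )

    def test_l1_asymptote(self):
        diff = 1e4
        loss = charbonnier(np.array([[diff]]), np.array([[0.0]])).item()
        assert loss / diff == pytest.approx(1.0, rel=1e-6)

    def test_lower_bound_sqrt_eps(self, rng):
        a, b = rng.random((4, 4)), rng.random((4, 4))
        assert charbonnier(a, b).item() >= 1e-2

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            charbonnier(np.zeros((2, 2)), np.zeros((3, 3)))


class TestSSIMLoss:
    def test_identical_images_zero(self, rng):
        img = rng.random((2, 1, 16, 16))
        assert ssim_loss(img, img).item() == pytest.approx(0.0, abs=1e-12)

    def test_one_minus_square_arithmetic(self, rng):
        # loss = mean(1 - s^2) for the per-image SSIM values s
        a = rng.random((3, 1, 16, 16))
        b = np.clip(a + rng.normal(0, 0.1, a.shape), 0, 1)
        s = ssim_per_image(a, b).data
        assert ssim_loss(a, b).item() == pytest.approx(float(np.mean(1 - s ** 2)), rel=1e-12)

    def test_uncorrelated_noise_near_one(self, rng):
        a = rng.random((1, 1, 32, 32))
        b = rng.random((1, 1, 32, 32))
        assert ssim_loss(a, b).item() > 0.8


class TestNIG:
    def test_omega_and_reg_identities(self):
        # beta=1, v=1 -> Omega=4; y=gamma kills the regulariser exactly
        y = np.array([0.3]); g = np.array([0.3])
        v = np.array([1.0]); a = np.array([2.0]); b = np.array([1.0])
        with_reg = nig_loss(y, g, v, a, b, lambda_reg=123.0).item()
        without = nig_loss(y, g, v, a, b, lambda_reg=0.0).item()
        assert with_reg == without  # L_Reg == 0 at y == gamma
        expected_nll = (0.5 * math.log(math.pi) - 2.0 * math.log(4.0)
                        + 2.5 * math.log(4.0) + math.lgamma(2.0) - math.lgamma(2.5))
        assert without == pytest.approx(expected_nll, rel=1e-12)

    def test_matches_scalar_oracle(self, rng):
        for _ in range(200):
            y, g = rng.normal(size=2)
            v, b = rng.gamma(2.0, 1.0, size=2) + 1e-3
            a = 1.0 + rng.gamma(2.0, 1.0) + 1e-3
            lam = rng.random()
            ours = nig_loss(np.array([y]), np.array([g]), np.array([v]),
                            np.array([a]), np.array([b]), lam).item()
            assert ours == pytest.approx(nig_scalar_oracle(y, g, v, a, b, lam), rel=1e-10)

    def test_gradient_stationary_at_y_equals_gamma(self):
        y = np.full((1,), 0.4)
        g = Tensor(np.full((1,), 0.4), requires_grad=True)
        nig_loss(y, g, np.array([1.5]), np.array([2.5]), np.array([0.8]),
                 lambda_reg=0.0).backward()
        eps = 1e-6
        f = lambda gv: nig_loss(y, np.array([gv]), np.array([1.5]), np.array([2.5]),
                                np.array([0.8]), 0.0).item()
        numeric = (f(0.4 + eps) - f(0.4 - eps)) / (2 * eps)
        assert g.grad[0] == pytest.approx(0.0, abs=1e-9)
        assert numeric == pytest.approx(0.0, abs=1e-6)

    def test_constraint_violation_rejected(self):
        ok = np.array([1.0])
        with pytest.raises(ValueError, match="constraints"):
            nig_loss(ok, ok, np.array([-1.0]), np.array([2.0]), ok)
        with pytest.raises(ValueError, match="constraints"):
            nig_loss(ok, ok, ok, np.array([1.0]), ok)


class TestCombined:
    def test_reduces_to_charbonnier(self, rng):
        a, b = rng.random((1, 1, 16, 16)), rng.random((1, 1, 16, 16))
        w = LossWeights(w1=0.0, w2=0.0)
        assert combined_loss(a, b, weights=w).item() == pytest.approx(
            charbonnier(a, b).item(), rel=1e-12
        )

    def test_identical_images_default_weights(self, rng):
        img = rng.random((1, 1, 16, 16))
        assert combined_loss(img, img).item() == pytest.approx(1e-2, rel=1e-10)

    def test_weighted_sum_on_toy_tensors(self, rng):
        pred = rng.random((1, 1, 16, 16))
        target = np.clip(pred + rng.normal(0, 0.05, pred.shape), 0, 1)
        maps = (Tensor(pred), Tensor(np.full_like(pred, 1.2)),
                Tensor(np.full_like(pred, 2.2)), Tensor(np.full_like(pred, 0.7)))
        w = LossWeights(w1=0.5, w2=1.0, lambda_reg=0.01)
        expected = (charbonnier(pred, target).item()
                    + 0.5 * ssim_loss(pred, target).item()
                    + nig_loss(target, *maps, lambda_reg=0.01).item())
        got = combined_loss(pred, target, evidential_maps=maps, weights=w).item()
        assert got == pytest.approx(expected, rel=1e-12)

    def test_losses_nonnegative_except_nig(self, rng):
        a, b = rng.random((1, 1, 16, 16)), rng.random((1, 1, 16, 16))
        assert charbonnier(a, b).item() >= 0
        assert ssim_loss(a, b).item() >= 0
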