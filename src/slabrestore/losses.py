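"""Training objectives: Charbonnier, squared-SSIM, and the evidential NIG loss.

The restoration objective combines a Charbonnier penalty

    L_Char = mean_i sqrt((HR_i - SR_i)^2 + eps),    eps = 1e-4,

(note: ``eps`` sits inside the root un-squared, so identical images give
``sqrt(eps) = 1e-2``, an L1 asymptote for large errors), with a
structure term that squares SSIM to sharpen its influence,

    L_SSIM = mean_i (1 - SSIM(SR_i, HR_i)^2),

weighted as ``L = L_Char + w1 L_SSIM`` with ``w1 = 0.5``.  When the
evidential head is active the Normal-Inverse-Gamma negative
log-likelihood plus an evidence regulariser is added with ``w2 = 1``:

    L_NIG = L_NLL + lambda * L_Reg,
    L_NLL = 1/2 log(pi/v) - alpha log(Om) + (alpha + 1/2) log((y-gamma)^2 v + Om)
            + log(Gamma(alpha)/Gamma(alpha + 1/2)),        Om = 2 beta (1 + v),
    L_Reg = |y - gamma| (2 v + alpha).

All functions accept numpy arrays or autodiff tensors and return a
scalar :class:`~slabrestore.nn.Tensor` (use ``.item()`` for the float).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.autograd import Tensor, lgamma, separable_filter2d

__all__ = ["LossWeights", "charbonnier", "ssim_loss", "nig_loss", "combined_loss"]

_SSIM_C1 = 0.01 ** 2  # (K1 * data_range)^2, data range 1
_SSIM_C2 = 0.03 ** 2


@dataclass(frozen=True)
class LossWeights:
    """Weights of the combined objective (defaults: w1=0.5, w2=1)."""

    w1: float = 0.5
    w2: float = 1.0
    lambda_reg: float = 0.01
    epsilon_char: float = 1e-4

    def __post_init__(self):
        if self.w1 < 0 or self.w2 < 0 or self.lambda_reg < 0:
            raise ValueError("loss weights must be nonnegative")
        if self.epsilon_char <= 0:
            raise ValueError("epsilon_char must be positive")


def _check_shapes(pred, target):
    pred = Tensor.as_tensor(pred)
    target = Tensor.as_tensor(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    return pred, target


def charbonnier(pred, target, eps: float = 1e-4) -> Tensor:
    """Mean of sqrt((pred - target)^2 + eps)."""
    pred, target = _check_shapes(pred, target)
    diff = pred - target
    return ((diff * diff + eps).sqrt()).mean()


def _gaussian_window(sigma: float = 1.5, radius: int = 5) -> np.ndarray:
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    k = np.exp(-(x ** 2) / (2.0 * sigma ** 2))
    return k / k.sum()


def ssim_per_image(pred, target, sigma: float = 1.5) -> Tensor:
    """Differentiable mean local SSIM per image of a (B, C, H, W) batch.

    11x11 Gaussian window (sigma 1.5), K1=0.01, K2=0.03, data range 1;
    windows are zero-padded at borders (identical images still score
    exactly 1 everywhere by symmetry of the SSIM ratio).
    """
    pred, target = _check_shapes(pred, target)
    if pred.ndim == 2:
        pred = pred.reshape((1, 1) + pred.shape)
        target = target.reshape((1, 1) + target.shape)
    elif pred.ndim == 3:
        pred = pred.reshape((1,) + pred.shape)
        target = target.reshape((1,) + target.shape)
    k = _gaussian_window(sigma)
    mu_x = separable_filter2d(pred, k)
    mu_y = separable_filter2d(target, k)
    sxx = separable_filter2d(pred * pred, k) - mu_x * mu_x
    syy = separable_filter2d(target * target, k) - mu_y * mu_y
    sxy = separable_filter2d(pred * target, k) - mu_x * mu_y
    num = (2.0 * mu_x * mu_y + _SSIM_C1) * (2.0 * sxy + _SSIM_C2)
    den = (mu_x * mu_x + mu_y * mu_y + _SSIM_C1) * (sxx + syy + _SSIM_C2)
    return (num / den).mean(axis=(1, 2, 3))


def ssim_loss(pred, target) -> Tensor:
    """Mean over the batch of 1 - SSIM^2 (SSIM taken per image/patch)."""
    s = ssim_per_image(pred, target)
    return (1.0 - s * s).mean()


def nig_loss(y, gamma, v, alpha, beta, lambda_reg: float = 0.01) -> Tensor:
    """Evidential Normal-Inverse-Gamma loss, mean over voxels.

    Raises if the hyperparameter domain constraints (v > 0, alpha > 1,
    beta > 0) are violated anywhere — that signals broken link
    functions upstream, not a recoverable input.
    """
    y = Tensor.as_tensor(y)
    gamma, v = Tensor.as_tensor(gamma), Tensor.as_tensor(v)
    alpha, beta = Tensor.as_tensor(alpha), Tensor.as_tensor(beta)
    if np.any(v.data <= 0) or np.any(alpha.data <= 1) or np.any(beta.data <= 0):
        raise ValueError("NIG constraints violated: require v > 0, alpha > 1, beta > 0")
    omega = 2.0 * beta * (1.0 + v)
    resid = y - gamma
    nll = (
        0.5 * (np.pi / v).log()
        - alpha * omega.log()
        + (alpha + 0.5) * (resid * resid * v + omega).log()
        + lgamma(alpha)
        - lgamma(alpha + 0.5)
    )
    reg = resid.abs() * (2.0 * v + alpha)
    return nll.mean() + lambda_reg * reg.mean()


def combined_loss(pred, target, evidential_maps=None,
                  weights: LossWeights = LossWeights()) -> Tensor:
    """Charbonnier + w1 * squared-SSIM loss (+ w2 * NIG when evidential).

    In evidential mode ``pred`` must be the gamma map and
    ``evidential_maps`` the (gamma, v, alpha, beta) tuple.
    """
    loss = charbonnier(pred, target, eps=weights.epsilon_char)
    if weights.w1 > 0:
        loss = loss + weights.w1 * ssim_loss(pred, target)
    if evidential_maps is not None and weights.w2 > 0:
        g, v, a, b = evidential_maps
        loss = loss + weights.w2 * nig_loss(target, g, v, a, b, weights.lambda_reg)
    return loss
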