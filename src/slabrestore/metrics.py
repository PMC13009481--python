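"""Image-quality metrics: PSNR and SSIM on [0, 1] volumes.

SSIM uses the standard 11x11 Gaussian window (sigma 1.5, K1=0.01,
K2=0.03, data range 1.0), computed per 2D slice of the requested
evaluation plane and averaged — matching per-direction reporting of 3D
reconstructions.  PSNR uses peak 1.0; identical volumes yield the
``inf`` sentinel.
"""

from __future__ import annotations

import numpy as np
from skimage.metrics import structural_similarity

from .volume import check_volume, plane_axis

__all__ = ["psnr", "ssim", "ssim_map", "quality_report"]


def _pair(a, b):
    a = check_volume(np.asarray(a, dtype=np.float64), "a") if np.ndim(a) == 3 else np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a, b


def psnr(a, b) -> float:
    """10 * log10(1 / MSE) in dB with peak 1.0 (inf for identical inputs)."""
    a, b = _pair(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(1.0 / mse))


def _ssim_2d(a2d: np.ndarray, b2d: np.ndarray, full: bool = False):
    return structural_similarity(
        a2d, b2d, win_size=11, gaussian_weights=True, sigma=1.5,
        use_sample_covariance=False, K1=0.01, K2=0.03, data_range=1.0,
        full=full,
    )


def ssim(a, b, plane: str = "sagittal") -> float:
    """Mean local SSIM, averaged over the slices of ``plane``."""
    return float(np.mean(ssim_per_slice(a, b, plane)))


def ssim_per_slice(a, b, plane: str = "sagittal") -> np.ndarray:
    # the slice score is the mean of the full local-SSIM map (borders
    # included), so it equals the SSIM map's mean by construction
    a, b = _pair(a, b)
    axis = plane_axis(plane)
    a_s = np.moveaxis(a, axis, 0)
    b_s = np.moveaxis(b, axis, 0)
    return np.array([_ssim_2d(x, y, full=True)[1].mean() for x, y in zip(a_s, b_s)])


def ssim_map(a, b, plane: str = "sagittal") -> np.ndarray:
    """Voxel-wise local SSIM map (same shape as the inputs)."""
    a, b = _pair(a, b)
    axis = plane_axis(plane)
    a_s = np.moveaxis(a, axis, 0)
    b_s = np.moveaxis(b, axis, 0)
    maps = np.stack([_ssim_2d(x, y, full=True)[1] for x, y in zip(a_s, b_s)])
    return np.moveaxis(maps, 0, axis)


def psnr_per_slice(a, b, plane: str = "sagittal") -> np.ndarray:
    a, b = _pair(a, b)
    axis = plane_axis(plane)
    mse = np.mean((np.moveaxis(a, axis, 0) - np.moveaxis(b, axis, 0)) ** 2, axis=(1, 2))
    with np.errstate(divide="ignore"):
        return 10.0 * np.log10(1.0 / mse)


def quality_report(pred, gt, plane: str = "sagittal") -> dict:
    """JSON-ready PSNR/SSIM report, per volume and per slice.

    Infinite PSNR (identical volumes) is rendered as the string
    sentinel ``"inf"``.
    """
    p = psnr(pred, gt)
    return {
        "plane": plane,
        "psnr_db": "inf" if np.isinf(p) else p,
        "ssim": ssim(pred, gt, plane),
        "psnr_per_slice": ["inf" if np.isinf(v) else float(v)
                           for v in psnr_per_slice(pred, gt, plane)],
        "ssim_per_slice": [float(v) for v in ssim_per_slice(pred, gt, plane)],
    }
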