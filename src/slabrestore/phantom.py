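"""Deterministic anatomy-like 3D phantoms.

The generator emulates the essentials of a T1-weighted brain volume that
the rest of the pipeline relies on: smooth nested tissue-like layers
(soft-edged ellipsoids with sigmoid falloff), a band-limited random
texture field so super-resolution has recoverable high-frequency detail,
optional additive noise, and a final rescale to [0, 1].  Identical specs
yield bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import rescale01

__all__ = ["PhantomSpec", "generate_phantom"]

_MIN_DIM = 8


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of a synthetic phantom volume.

    Parameters
    ----------
    shape : tuple of int
        Volume dimensions (FE, PE, SL); each must be >= 8.
    seed : int
        Seed for every random element (ellipsoid jitter, texture, noise).
    n_ellipsoids : int
        Number of nested soft-edged ellipsoid shells (tissue layers).
    texture_scale : float
        Correlation length, in voxels, of the smooth random texture field.
    noise_sd : float
        Standard deviation of additive Gaussian noise (before rescaling).
    """

    shape: tuple = (64, 64, 32)
    seed: int = 0
    n_ellipsoids: int = 4
    texture_scale: float = 2.0
    noise_sd: float = 0.01

    def __post_init__(self):
        if len(self.shape) != 3 or any(int(d) < _MIN_DIM for d in self.shape):
            raise ValueError(
                f"phantom shape must be a 3D triple with every dim >= {_MIN_DIM}; got {self.shape}"
            )
        if self.n_ellipsoids < 1:
            raise ValueError("n_ellipsoids must be >= 1")
        if self.texture_scale <= 0:
            raise ValueError("texture_scale must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _ellipsoid_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    shape = np.array(spec.shape, dtype=float)
    grid = np.meshgrid(*(np.arange(n, dtype=float) for n in spec.shape), indexing="ij")
    center = (shape - 1) / 2.0
    field = np.zeros(spec.shape, dtype=np.float64)
    # outermost shell spans ~90% of the half-extent, inner shells shrink
    for k in range(spec.n_ellipsoids):
        frac = 0.9 * (1.0 - k / (spec.n_ellipsoids + 1))
        semi = np.maximum(frac * shape / 2.0, 1.5)
        jitter = rng.uniform(-0.04, 0.04, size=3) * shape
        q = sum(((g - c - j) / s) ** 2 for g, c, j, s in zip(grid, center, jitter, semi))
        # sigmoid falloff across the shell boundary (soft edge ~1.5 voxels)
        edge = 1.5 / float(np.min(semi))
        weight = rng.uniform(0.4, 1.0) * (1 if k % 2 == 0 else -0.6)
        field += weight / (1.0 + np.exp((np.sqrt(q) - 1.0) / edge))
    return field


def _texture_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(spec.shape)
    smooth = ndimage.gaussian_filter(white, sigma=spec.texture_scale, mode="wrap")
    peak = np.max(np.abs(smooth))
    return smooth / peak if peak > 0 else smooth


def generate_phantom(spec: PhantomSpec) -> np.ndarray:
    """Generate the phantom volume described by *spec*.

    Returns a float64 array of ``spec.shape`` with min 0 and max 1
    (unless the construction degenerates to a constant, which rescales
    to all zeros).
    """
    rng = np.random.default_rng(spec.seed)
    vol = _ellipsoid_field(spec, rng)
    # texture only inside the head: modulate by the (positive) anatomy envelope
    envelope = rescale01(vol)
    vol = vol + 0.15 * _texture_field(spec, rng) * (0.2 + envelope)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)
    return rescale01(vol)
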