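"""Thin-slab residual channel-attention restoration network.

A 2D RCAN-style backbone whose input and output channel dimensions
carry the through-plane slices of a thin slab: an ``M``-slice slab
enters as ``M`` channels, so the first 3x3 convolution acts like a 3D
kernel that never strides along the slice axis, and the final
convolution emits ``N`` output slices (``N = M * s_sl`` for
super-resolution, ``N = M`` for motion-artifact reduction).  Optional
sub-pixel (pixel-shuffle) upsampling provides in-plane scaling, and an
optional evidential head emits four Normal-Inverse-Gamma hyperparameter
maps (gamma, v, alpha, beta) per output slice through positive link
functions (v, beta via softplus; alpha = 1 + softplus).
"""

from __future__ import annotations

import json
from collections import namedtuple
from dataclasses import asdict, dataclass

import numpy as np

from .autograd import Tensor, conv2d, pixel_shuffle

__all__ = ["NetworkConfig", "ThinSlabRCAN", "NIGTensors", "build_model"]

NIGTensors = namedtuple("NIGTensors", "gamma v alpha beta")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    Defaults follow the full-scale configuration (5 residual groups of
    5 residual channel-attention blocks, 64 filters, reduction 16); the
    tiny variants used in tests shrink ``n_rg``/``n_rcab``/``n_feat``.
    """

    M: int = 3
    N: int = 3
    n_rg: int = 5
    n_rcab: int = 5
    n_feat: int = 64
    reduction: int = 16
    inplane_scale: int = 1
    evidential: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_feat % self.reduction != 0:
            raise ValueError(
                f"n_feat={self.n_feat} must be divisible by reduction={self.reduction}"
            )
        if self.inplane_scale not in (1, 2, 4):
            raise ValueError("inplane_scale must be 1, 2 or 4")
        if min(self.M, self.N, self.n_rg, self.n_rcab, self.n_feat) < 1:
            raise ValueError("M, N, n_rg, n_rcab, n_feat must be positive")

    @property
    def out_channels(self) -> int:
        return 4 * self.N if self.evidential else self.N


class _Conv:
    """3x3 (or 1x1) convolution with He-initialized weights."""

    def __init__(self, rng, cin: int, cout: int, k: int = 3):
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Tensor(rng.normal(0.0, std, size=(cout, cin, k, k)), requires_grad=True)
        self.b = Tensor(np.zeros(cout), requires_grad=True)
        self.pad = (k - 1) // 2

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, pad=self.pad)

    @property
    def params(self):
        return [self.w, self.b]


class _RCAB:
    """conv-ReLU-conv followed by a squeeze-excitation channel gate."""

    def __init__(self, rng, n_feat: int, reduction: int):
        self.c1 = _Conv(rng, n_feat, n_feat)
        self.c2 = _Conv(rng, n_feat, n_feat)
        self.d1 = _Conv(rng, n_feat, n_feat // reduction, k=1)
        self.d2 = _Conv(rng, n_feat // reduction, n_feat, k=1)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.c2(self.c1(x).relu())
        gate = self.d2(self.d1(h.mean(axis=(2, 3), keepdims=True)).relu()).sigmoid()
        return x + h * gate

    def attention_gate(self, x: Tensor) -> np.ndarray:
        h = self.c2(self.c1(x).relu())
        return self.d2(self.d1(h.mean(axis=(2, 3), keepdims=True)).relu()).sigmoid().data

    @property
    def params(self):
        return self.c1.params + self.c2.params + self.d1.params + self.d2.params


class _ResidualGroup:
    def __init__(self, rng, n_feat: int, n_rcab: int, reduction: int):
        self.blocks = [_RCAB(rng, n_feat, reduction) for _ in range(n_rcab)]
        self.tail = _Conv(rng, n_feat, n_feat)

    def __call__(self, x: Tensor) -> Tensor:
        h = x
        for block in self.blocks:
            h = block(h)
        return x + self.tail(h)

    @property
    def params(self):
        out = []
        for block in self.blocks:
            out += block.params
        return out + self.tail.params


class ThinSlabRCAN:
    """Fully convolutional restoration model over thin-slab inputs.

    Deterministic given ``cfg.seed``: all weights are drawn from a
    generator seeded with it.
    """

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.n_feat
        self.head = _Conv(rng, cfg.M, f)
        self.groups = [
            _ResidualGroup(rng, f, cfg.n_rcab, cfg.reduction) for _ in range(cfg.n_rg)
        ]
        self.body_tail = _Conv(rng, f, f)
        self.upsamplers = []
        s = cfg.inplane_scale
        while s > 1:  # one x2 pixel-shuffle stage per factor of 2
            self.upsamplers.append(_Conv(rng, f, 4 * f))
            s //= 2
        self.tail = _Conv(rng, f, cfg.out_channels)

    # -- forward -----------------------------------------------------------
    def _features(self, x: Tensor) -> Tensor:
        shallow = self.head(x)
        h = shallow
        for g in self.groups:
            h = g(h)
        h = shallow + self.body_tail(h)  # global skip from shallow features
        for up in self.upsamplers:
            h = pixel_shuffle(up(h), 2)
        return h

    def forward(self, slab) -> Tensor | tuple:
        """Restore a slab batch (B, M, H, W).

        Returns the restored slab (B, N, H*r, W*r); in evidential mode,
        a ``(restored, NIGTensors)`` pair where the restored image is
        the gamma map.
        """
        x = Tensor.as_tensor(slab)
        if x.ndim == 3:
            x = x.reshape((1,) + x.shape)
        if x.shape[1] != self.cfg.M:
            raise ValueError(f"expected {self.cfg.M} input channels, got {x.shape[1]}")
        out = self.tail(self._features(x))
        if not self.cfg.evidential:
            return out
        n = self.cfg.N
        # 1e-6 floor keeps v > 0 and alpha > 1 strict even when softplus
        # underflows to zero in float64
        gamma = out[:, 0:n]
        v = out[:, n:2 * n].softplus() + 1e-6
        alpha = 1.0 + out[:, 2 * n:3 * n].softplus() + 1e-6
        beta = out[:, 3 * n:4 * n].softplus() + 1e-6
        return gamma, NIGTensors(gamma, v, alpha, beta)

    __call__ = forward

    # -- parameters ----------------------------------------------------------
    @property
    def params(self):
        out = self.head.params
        for g in self.groups:
            out += g.params
        out += self.body_tail.params
        for up in self.upsamplers:
            out += up.params
        return out + self.tail.params

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    # -- checkpoints ---------------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {f"p{i}": p.data for i, p in enumerate(self.params)}
        arrays["config_json"] = np.array(json.dumps(asdict(self.cfg)))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "ThinSlabRCAN":
        with np.load(path, allow_pickle=False) as f:
            cfg = NetworkConfig(**json.loads(str(f["config_json"])))
            model = cls(cfg)
            for i, p in enumerate(model.params):
                data = f[f"p{i}"]
                if data.shape != p.data.shape:
                    raise ValueError("checkpoint does not match the network config")
                p.data = data.astype(np.float64)
        return model


def build_model(cfg: NetworkConfig) -> ThinSlabRCAN:
    """Construct a :class:`ThinSlabRCAN` from its configuration."""
    return ThinSlabRCAN(cfg)
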