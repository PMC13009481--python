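"""End-to-end orchestration: pair synthesis, training, slab inference.

Training follows the reference schedule — ADAM (beta1=0.9, beta2=0.999,
eps=1e-8), cosine learning-rate decay from 1e-4 to 1e-8, 50 epochs,
batches of eight randomly drawn LR patches — on pairs built either by
k-space truncation (super-resolution) or periodic motion corruption
(artifact reduction).  Inference extracts thin slabs and in-plane
patches, runs the network, tiles the central patch regions, and
averages the up-to-``M`` overlapping slab candidates per slice
(self-ensemble).

:class:`SlabRestorer` wraps the whole procedure as a scikit-learn style
estimator (``fit`` on ground-truth volumes, ``transform`` on degraded
ones); the module-level :func:`train` and :func:`infer` remain thin
functional entry points.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import List, Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .kspace import ScaleFactor, degrade_lr
from .losses import LossWeights, combined_loss
from .metrics import psnr
from .motionsim import MotionSchedule, corrupt
from .nn import Adam, NetworkConfig, Tensor, ThinSlabRCAN, cosine_lr
from .slab import PatchGeometry, extract_patch_pairs, grid_starts, stitch
from .uncertainty import EvidentialMaps, UncertaintyMaps, moments
from .volume import check_volume, rescale01

__all__ = [
    "TrainConfig", "train", "infer", "restore_volume", "make_pairs",
    "SlabRestorer", "srr_grid", "mar_grid",
]


@dataclass(frozen=True)
class TrainConfig:
    """Full training recipe (defaults reproduce the reference schedule)."""

    task: str = "srr"                      # "srr" or "mar"
    scale: ScaleFactor = field(default_factory=ScaleFactor)
    motion: Optional[MotionSchedule] = None
    M: int = 3
    plane: str = ""                        # "" -> srr: sagittal, mar: axial
    lr_size: int = 0                       # 0 -> 128/32 HR grid defaults
    lr_overlap: int = 0
    epochs: int = 50
    steps_per_epoch: int = 0               # 0 -> n_pairs // batch
    batch: int = 8
    lr: float = 1e-4
    lr_min: float = 1e-8
    betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8
    weights: LossWeights = field(default_factory=LossWeights)
    evidential: bool = False
    n_rg: int = 5
    n_rcab: int = 5
    n_feat: int = 64
    reduction: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.task not in ("srr", "mar"):
            raise ValueError(f"task must be 'srr' or 'mar'; got {self.task!r}")
        object.__setattr__(self, "scale", ScaleFactor.parse(self.scale))
        if not self.plane:
            object.__setattr__(self, "plane", "sagittal" if self.task == "srr" else "axial")
        if self.task == "mar" and self.motion is None:
            object.__setattr__(self, "motion", MotionSchedule())

    @property
    def geometry(self) -> PatchGeometry:
        scale = self.scale if self.task == "srr" else ScaleFactor(1, 1, 1)
        return PatchGeometry(scale=scale, M=self.M, plane=self.plane,
                             lr_size=self.lr_size, lr_overlap=self.lr_overlap)

    def network_config(self) -> NetworkConfig:
        geom = self.geometry
        return NetworkConfig(
            M=self.M, N=geom.N, n_rg=self.n_rg, n_rcab=self.n_rcab,
            n_feat=self.n_feat, reduction=self.reduction,
            inplane_scale=geom.inplane_scale, evidential=self.evidential,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scale"] = list(self.scale)
        d["motion"] = asdict(self.motion) if self.motion else None
        d["weights"] = asdict(self.weights)
        d["betas"] = list(self.betas)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        d = dict(d)
        d["scale"] = ScaleFactor.parse(d["scale"])
        if d.get("motion"):
            d["motion"] = MotionSchedule(**d["motion"])
        d["weights"] = LossWeights(**d["weights"])
        d["betas"] = tuple(d["betas"])
        return cls(**d)


def make_pairs(volumes: Sequence[np.ndarray], cfg: TrainConfig):
    """Degrade ground-truth volumes and crop matched patch pairs."""
    geom = cfg.geometry
    pairs = []
    for vol in volumes:
        hr = rescale01(check_volume(vol))
        if cfg.task == "srr":
            lr = degrade_lr(hr, cfg.scale)
        else:
            lr = corrupt(hr, cfg.motion, slice_axis=geom.through_axis)
        pairs.extend(extract_patch_pairs(hr, lr, geom))
    return pairs


def _batch(pairs, idx):
    x = np.stack([pairs[i].lr for i in idx])
    y = np.stack([pairs[i].hr for i in idx])
    return x, y


def train(cfg: TrainConfig, volumes: Sequence[np.ndarray],
          val_volumes: Sequence[np.ndarray] = (), verbose: bool = False):
    """Train a thin-slab network on degraded/clean pairs.

    Returns ``(model, history)``; ``history`` carries the serialized
    config, the per-step loss and learning-rate traces, and per-epoch
    validation PSNR on held-out patches when ``val_volumes`` is given.
    Aborts with a diagnostic on a non-finite loss.
    """
    pairs = make_pairs(volumes, cfg)
    if not pairs:
        raise ValueError("empty training stream")
    val_pairs = make_pairs(val_volumes, cfg) if len(val_volumes) else []
    rng = np.random.default_rng(cfg.seed)
    model = ThinSlabRCAN(cfg.network_config())
    opt = Adam(model.params, lr=cfg.lr, betas=cfg.betas, eps=cfg.adam_eps)

    spe = cfg.steps_per_epoch or max(1, len(pairs) // cfg.batch)
    total = cfg.epochs * spe
    history = {"config": cfg.to_dict(), "loss": [], "lr": [], "val_psnr": []}
    order = rng.permutation(len(pairs))
    cursor = 0
    for step in range(total):
        if cursor + cfg.batch > len(order):
            order = rng.permutation(len(pairs))
            cursor = 0
        idx = order[cursor:cursor + cfg.batch]
        cursor += cfg.batch
        x, y = _batch(pairs, idx)
        out = model(x)
        if cfg.evidential:
            pred, maps = out
            loss = combined_loss(pred, y, evidential_maps=maps, weights=cfg.weights)
        else:
            loss = combined_loss(out, y, weights=cfg.weights)
        lval = loss.item()
        if not np.isfinite(lval):
            raise RuntimeError(
                f"non-finite loss at step {step} (lr={opt.lr:.3g}, "
                f"batch mean={x.mean():.4f}, sd={x.std():.4f})"
            )
        opt.zero_grad()
        loss.backward()
        opt.lr = cosine_lr(step, total, cfg.lr, cfg.lr_min)
        opt.step()
        history["loss"].append(lval)
        history["lr"].append(opt.lr)
        if val_pairs and (step + 1) % spe == 0:
            history["val_psnr"].append(_validate(model, val_pairs, cfg))
            if verbose:
                epoch = (step + 1) // spe
                print(f"epoch {epoch}: loss={lval:.4f} "
                      f"val_psnr={history['val_psnr'][-1]:.2f} dB")
    return model, history


def _validate(model, val_pairs, cfg, max_pairs: int = 16) -> float:
    rng = np.random.default_rng(cfg.seed + 1)
    idx = rng.choice(len(val_pairs), size=min(max_pairs, len(val_pairs)), replace=False)
    x, y = _batch(val_pairs, idx)
    out = model(x)
    pred = out[0] if cfg.evidential else out
    pred = np.clip(pred.data if isinstance(pred, Tensor) else pred, 0.0, 1.0)
    return float(np.mean([psnr(p, t) for p, t in zip(pred, y)]))


def restore_volume(model, volume: np.ndarray, geom: PatchGeometry,
                   ensemble: bool = True, batch_size: int = 8):
    """Full-volume inference: extract -> forward -> stitch (-> ensemble).

    ``model`` is a :class:`ThinSlabRCAN` or any callable mapping a slab
    batch (B, M, h, w) to (B, N, H, W).  Returns the restored volume
    clipped to [0, 1]; in evidential mode, a ``(restored,
    UncertaintyMaps)`` pair whose maps pass through the same stitching.
    """
    volume = check_volume(volume)
    lr_s = np.moveaxis(volume, geom.through_axis, 0)
    d_lr = lr_s.shape[0]
    if geom.M > d_lr:
        raise ValueError(f"M={geom.M} exceeds volume depth {d_lr}")
    ys = grid_starts(lr_s.shape[1], geom.lr_size, geom.lr_overlap)
    xs = grid_starts(lr_s.shape[2], geom.lr_size, geom.lr_overlap)
    coords = [(s, y, x) for s in range(d_lr - geom.M + 1) for y in ys for x in xs]

    evidential = getattr(getattr(model, "cfg", None), "evidential", False)
    outs, ale, epi = [], [], []
    for i in range(0, len(coords), batch_size):
        chunk = coords[i:i + batch_size]
        x = np.stack([lr_s[s:s + geom.M, y:y + geom.lr_size, x0:x0 + geom.lr_size]
                      for s, y, x0 in chunk])
        out = model(x)
        if evidential:
            pred, maps = out
            g, v, a, b = (t.data for t in maps)
            _, u = moments(EvidentialMaps(g, v, a, b))
            for j, (s, y, x0) in enumerate(chunk):
                outs.append((s, y, x0, pred.data[j]))
                ale.append((s, y, x0, u.aleatoric[j]))
                epi.append((s, y, x0, u.epistemic[j]))
        else:
            data = out.data if isinstance(out, Tensor) else np.asarray(out)
            for j, (s, y, x0) in enumerate(chunk):
                outs.append((s, y, x0, data[j]))

    r, ts = geom.inplane_scale, geom.through_scale
    target_shape = list(volume.shape)
    for ax in geom.inplane_axes:
        target_shape[ax] *= r
    target_shape[geom.through_axis] *= ts
    target_shape = tuple(target_shape)

    restored = np.clip(stitch(outs, target_shape, geom, ensemble=ensemble), 0.0, 1.0)
    if not evidential:
        return restored
    maps = UncertaintyMaps(
        aleatoric=stitch(ale, target_shape, geom, ensemble=ensemble),
        epistemic=stitch(epi, target_shape, geom, ensemble=ensemble),
    )
    return restored, maps


def infer(model, volume, geom: PatchGeometry, self_ensemble: bool = True):
    """Alias of :func:`restore_volume` with the spec's argument order."""
    return restore_volume(model, volume, geom, ensemble=self_ensemble)


class SlabRestorer(BaseEstimator, TransformerMixin):
    """Scikit-learn style front end to the thin-slab restoration pipeline.

    ``fit(X)`` takes a list of clean [0, 1] volumes, synthesises the
    degraded counterparts (k-space truncation for ``task="srr"``,
    periodic motion corruption for ``task="mar"``), and trains the
    network; ``transform(X)`` restores degraded volumes with slab
    self-ensembling.  All constructor arguments are plain values so the
    estimator composes with ``sklearn`` model selection.
    """

    def __init__(self, task: str = "srr", scale=(1, 1, 2), ts_in_eg: int = 9,
                 eg: int = 80, angle_inplane_deg: float = 5.0,
                 angle_throughplane_deg: float = 0.0, M: int = 3,
                 lr_size: int = 0, lr_overlap: int = 0, epochs: int = 50,
                 steps_per_epoch: int = 0, batch: int = 8, lr: float = 1e-4,
                 lr_min: float = 1e-8, w1: float = 0.5, w2: float = 1.0,
                 lambda_reg: float = 0.01, evidential: bool = False,
                 n_rg: int = 5, n_rcab: int = 5, n_feat: int = 64,
                 reduction: int = 16, ensemble: bool = True, seed: int = 0):
        self.task = task
        self.scale = scale
        self.ts_in_eg = ts_in_eg
        self.eg = eg
        self.angle_inplane_deg = angle_inplane_deg
        self.angle_throughplane_deg = angle_throughplane_deg
        self.M = M
        self.lr_size = lr_size
        self.lr_overlap = lr_overlap
        self.epochs = epochs
        self.steps_per_epoch = steps_per_epoch
        self.batch = batch
        self.lr = lr
        self.lr_min = lr_min
        self.w1 = w1
        self.w2 = w2
        self.lambda_reg = lambda_reg
        self.evidential = evidential
        self.n_rg = n_rg
        self.n_rcab = n_rcab
        self.n_feat = n_feat
        self.reduction = reduction
        self.ensemble = ensemble
        self.seed = seed

    def _config(self) -> TrainConfig:
        motion = None
        if self.task == "mar":
            motion = MotionSchedule(
                ts_in_eg=self.ts_in_eg, eg=self.eg,
                angle_inplane_deg=self.angle_inplane_deg,
                angle_throughplane_deg=self.angle_throughplane_deg,
            )
        return TrainConfig(
            task=self.task, scale=ScaleFactor.parse(self.scale), motion=motion,
            M=self.M, lr_size=self.lr_size, lr_overlap=self.lr_overlap,
            epochs=self.epochs, steps_per_epoch=self.steps_per_epoch,
            batch=self.batch, lr=self.lr, lr_min=self.lr_min,
            weights=LossWeights(w1=self.w1, w2=self.w2, lambda_reg=self.lambda_reg),
            evidential=self.evidential, n_rg=self.n_rg, n_rcab=self.n_rcab,
            n_feat=self.n_feat, reduction=self.reduction, seed=self.seed,
        )

    def fit(self, X, y=None, val_volumes=()):
        cfg = self._config()
        self.model_, self.history_ = train(cfg, X, val_volumes=val_volumes)
        self.config_ = cfg
        self.geometry_ = cfg.geometry
        return self

    def transform(self, X):
        """Restore one degraded volume or a list of them."""
        check_is_fitted(self, "model_")
        single = isinstance(X, np.ndarray) and X.ndim == 3
        volumes = [X] if single else list(X)
        results = [restore_volume(self.model_, v, self.geometry_,
                                  ensemble=self.ensemble) for v in volumes]
        if self.evidential:
            results = [r[0] for r in results]
        return results[0] if single else results

    def transform_with_uncertainty(self, X):
        """Restore a volume and return its (aleatoric, epistemic) maps."""
        check_is_fitted(self, "model_")
        if not self.evidential:
            raise ValueError("uncertainty maps require evidential=True")
        return restore_volume(self.model_, X, self.geometry_, ensemble=self.ensemble)


def srr_grid() -> List[dict]:
    """The super-resolution factor grid: {2x2x1, 1x1x2} and {4x4x1, 2x2x2, 1x1x4}
    crossed with M in {1, 3, 5} and the self-ensemble flag."""
    factors = [(2, 2, 1), (1, 1, 2), (4, 4, 1), (2, 2, 2), (1, 1, 4)]
    return [{"scale": ScaleFactor(*f), "M": m, "self_ensemble": se}
            for f in factors for m in (1, 3, 5) for se in (False, True)]


def mar_grid() -> List[dict]:
    """The motion grid: Ts in {9, 18, 36, 72} EG crossed with M in {1, 3}."""
    return [{"ts_in_eg": ts, "M": m} for ts in (9, 18, 36, 72) for m in (1, 3)]
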