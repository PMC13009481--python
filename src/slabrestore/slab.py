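"""Thin-slab and patch geometry.

A volume is processed as overlapping *thin slabs* of ``M`` adjacent
slices mapped to network channels, each slab cut into overlapping
in-plane patches.  At inference the patch outputs are re-assembled by
discarding border regions and tiling the central areas; every slice is
reconstructed by up to ``M`` slab positions, and the self-ensemble is
the voxel-wise average of those candidates.

In-plane seams are resolved by cutting each overlap at its midpoint,
which for a regular grid equals discarding ``overlap/2`` per side while
edge patches keep their outer borders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .kspace import ScaleFactor
from .volume import check_volume, plane_axis

__all__ = [
    "PatchGeometry",
    "extract_slabs",
    "extract_patch_pairs",
    "grid_starts",
    "stitch",
    "self_ensemble",
]

_ALLOWED_M = (1, 3, 5)


@dataclass(frozen=True)
class PatchGeometry:
    """Patch/slab geometry for one restoration task.

    ``plane`` fixes the through-plane (slab) axis; the scale factor's
    components along the two in-plane axes must be equal and give the
    network's in-plane upscaling, while the through-plane component
    multiplies the slice count (``N = M * through_scale``).  Default
    patch sizes follow the 128/32 high-resolution grid: LR patches are
    ``128/r`` with ``32/r`` overlap for in-plane scale ``r``.
    """

    scale: ScaleFactor = field(default_factory=ScaleFactor)
    M: int = 3
    plane: str = "sagittal"
    lr_size: int = 0      # 0 -> derived from the 128/32 HR grid
    lr_overlap: int = 0

    def __post_init__(self):
        sf = ScaleFactor.parse(self.scale)
        object.__setattr__(self, "scale", sf)
        plane_axis(self.plane)
        if self.M not in _ALLOWED_M:
            raise ValueError(f"M must be one of {_ALLOWED_M}; got {self.M}")
        axes = [sf.s_fe, sf.s_pe, sf.s_sl]
        ip = [axes[a] for a in self.inplane_axes]
        if ip[0] != ip[1]:
            raise ValueError(f"in-plane scale components must match; got {ip}")
        if self.lr_size == 0:
            object.__setattr__(self, "lr_size", 128 // ip[0])
            object.__setattr__(self, "lr_overlap", 32 // ip[0])
        if not (0 <= self.lr_overlap < self.lr_size):
            raise ValueError("need 0 <= lr_overlap < lr_size")

    @property
    def through_axis(self) -> int:
        return plane_axis(self.plane)

    @property
    def inplane_axes(self) -> Tuple[int, int]:
        return tuple(a for a in range(3) if a != self.through_axis)

    @property
    def inplane_scale(self) -> int:
        return [self.scale.s_fe, self.scale.s_pe, self.scale.s_sl][self.inplane_axes[0]]

    @property
    def through_scale(self) -> int:
        return [self.scale.s_fe, self.scale.s_pe, self.scale.s_sl][self.through_axis]

    @property
    def N(self) -> int:
        """Output slices per slab."""
        return self.M * self.through_scale

    @property
    def hr_size(self) -> int:
        return self.lr_size * self.inplane_scale

    @property
    def hr_overlap(self) -> int:
        return self.lr_overlap * self.inplane_scale


@dataclass(frozen=True)
class PatchPair:
    lr: np.ndarray         # (M, h, w)
    hr: np.ndarray         # (N, h*r, w*r)
    slab_start: int        # LR through-plane start
    y: int                 # LR in-plane starts
    x: int


def _to_slices_first(volume: np.ndarray, axis: int) -> np.ndarray:
    return np.moveaxis(volume, axis, 0)


def extract_slabs(volume: np.ndarray, M: int, stride: int = 1, axis: int = 2):
    """Enumerate (start, slab) pairs of ``M`` contiguous slices.

    At the default stride 1 consecutive slabs share ``M - 1`` slices and
    there are ``D - M + 1`` slabs for depth ``D``.
    """
    volume = check_volume(volume)
    if M not in _ALLOWED_M:
        raise ValueError(f"M must be one of {_ALLOWED_M}; got {M}")
    stacked = _to_slices_first(volume, axis)
    depth = stacked.shape[0]
    if M > depth:
        raise ValueError(f"slab thickness M={M} exceeds depth {depth}")
    return [(s, stacked[s:s + M]) for s in range(0, depth - M + 1, stride)]


def grid_starts(length: int, size: int, overlap: int) -> List[int]:
    """Start offsets of an overlapping 1D patch grid covering [0, length).

    The grid steps by ``size - overlap``; if it does not tile exactly,
    the final patch is shifted to end at the boundary (its overlap with
    the previous patch grows locally).
    """
    if size > length:
        raise ValueError(f"patch size {size} exceeds extent {length}")
    stride = size - overlap
    starts = list(range(0, length - size + 1, stride))
    if starts[-1] + size < length:
        starts.append(length - size)
    return starts


def extract_patch_pairs(hr: np.ndarray, lr: np.ndarray, geom: PatchGeometry) -> List[PatchPair]:
    """Crop matched (LR slab patch, HR slab patch) training pairs.

    LR patches have ``geom.lr_size`` in-plane extent with
    ``geom.lr_overlap`` overlap and ``M`` slices; HR patches are the
    corresponding region scaled by the in-plane factor with
    ``N = M * through_scale`` slices.
    """
    hr = check_volume(hr, "hr")
    lr = check_volume(lr, "lr")
    r, ts = geom.inplane_scale, geom.through_scale
    scale_by_axis = {geom.inplane_axes[0]: r, geom.inplane_axes[1]: r,
                     geom.through_axis: ts}
    for ax in range(3):
        if hr.shape[ax] != lr.shape[ax] * scale_by_axis[ax]:
            name = "FE PE SL".split()[ax]
            raise ValueError(
                f"HR/LR shape mismatch along {name}: {hr.shape[ax]} != "
                f"{lr.shape[ax]} * {scale_by_axis[ax]}"
            )
    lr_s = _to_slices_first(lr, geom.through_axis)
    hr_s = _to_slices_first(hr, geom.through_axis)
    d_lr = lr_s.shape[0]
    if geom.M > d_lr:
        raise ValueError(f"M={geom.M} exceeds LR depth {d_lr}")
    ys = grid_starts(lr_s.shape[1], geom.lr_size, geom.lr_overlap)
    xs = grid_starts(lr_s.shape[2], geom.lr_size, geom.lr_overlap)
    pairs = []
    for s in range(d_lr - geom.M + 1):
        for y in ys:
            for x in xs:
                lrp = lr_s[s:s + geom.M, y:y + geom.lr_size, x:x + geom.lr_size]
                hrp = hr_s[s * ts:s * ts + geom.N,
                           y * r:(y + geom.lr_size) * r,
                           x * r:(x + geom.lr_size) * r]
                pairs.append(PatchPair(lr=lrp, hr=hrp, slab_start=s, y=y, x=x))
    return pairs


def _cut_bounds(starts: Sequence[int], size: int, length: int) -> List[Tuple[int, int]]:
    """Midpoint cuts between overlapping patches along one axis."""
    bounds = []
    prev = 0
    for i, s in enumerate(starts):
        if i + 1 < len(starts):
            nxt = (s + size + starts[i + 1]) // 2
        else:
            nxt = length
        bounds.append((prev, nxt))
        prev = nxt
    if bounds[-1][1] != length or bounds[0][0] != 0:
        raise ValueError("patch grid does not cover the plane")
    return bounds


def stitch(outputs, target_shape, geom: PatchGeometry, ensemble: bool = True) -> np.ndarray:
    """Re-assemble patch outputs into a full volume.

    ``outputs`` is an iterable of ``(slab_start, y, x, patch)`` with
    patch arrays of shape ``(N, hr_size, hr_size)`` and LR-grid
    coordinates.  In-plane, each patch contributes the central region up
    to the overlap midpoints (edge patches keep their borders).
    Through-plane, every output slice is produced by up to ``M`` slab
    positions: with ``ensemble=True`` those candidates are voxel-wise
    averaged; otherwise the slab in which the slice sits most centrally
    is used.
    """
    r, ts = geom.inplane_scale, geom.through_scale
    by_slab = {}
    for s, y, x, patch in outputs:
        by_slab.setdefault(s, []).append((y, x, np.asarray(patch, dtype=np.float64)))
    if not by_slab:
        raise ValueError("no patch outputs to stitch")

    out_shape_s = tuple(np.moveaxis(np.empty(target_shape, dtype=bool),
                                    geom.through_axis, 0).shape)
    d_hr, H, W = out_shape_s
    d_lr = d_hr // ts
    expected = set(range(d_lr - geom.M + 1))
    missing = expected - set(by_slab)
    if missing:
        raise ValueError(f"coverage gap: no outputs for slab starts {sorted(missing)}")

    ys = sorted({y for planes in by_slab.values() for y, _, _ in planes})
    xs = sorted({x for planes in by_slab.values() for _, x, _ in planes})
    hy = [y * r for y in ys]
    hx = [x * r for x in xs]
    ybounds = dict(zip(hy, _cut_bounds(hy, geom.hr_size, H)))
    xbounds = dict(zip(hx, _cut_bounds(hx, geom.hr_size, W)))

    planes = {}
    for s, items in by_slab.items():
        plane = np.zeros((geom.N, H, W), dtype=np.float64)
        filled = np.zeros((H, W), dtype=bool)
        for y, x, patch in items:
            y0, y1 = ybounds[y * r]
            x0, x1 = xbounds[x * r]
            plane[:, y0:y1, x0:x1] = patch[:, y0 - y * r:y1 - y * r,
                                           x0 - x * r:x1 - x * r]
            filled[y0:y1, x0:x1] = True
        if not filled.all():
            raise ValueError(f"coverage gap in slab {s}: {int((~filled).sum())} "
                             "in-plane voxels uncovered")
        planes[s] = plane

    # center assignment: each slice taken from the slab where it sits most
    # centrally (complete coverage by construction)
    out = np.zeros(out_shape_s, dtype=np.float64)
    half = (geom.M - 1) // 2
    for j in range(d_hr):
        parent = j // ts
        s = int(np.clip(parent - half, 0, d_lr - geom.M))
        out[j] = planes[s][j - s * ts]
    if ensemble:
        # average the up-to-M candidates per slice as center + mean deviation,
        # so identical candidates reproduce the center value bit-exactly
        dev = np.zeros(out_shape_s, dtype=np.float64)
        count = np.zeros(d_hr, dtype=np.int64)
        for s, plane in planes.items():
            dev[s * ts:s * ts + geom.N] += plane - out[s * ts:s * ts + geom.N]
            count[s * ts:s * ts + geom.N] += 1
        out += dev / count[:, None, None]
    return np.moveaxis(out, 0, geom.through_axis)


def self_ensemble(candidates: Sequence[np.ndarray]) -> np.ndarray:
    """Unweighted voxel-wise mean of equally shaped reconstructions."""
    if len(candidates) == 0:
        raise ValueError("self_ensemble needs at least one candidate")
    first = np.asarray(candidates[0], dtype=np.float64)
    for c in candidates[1:]:
        if np.shape(c) != first.shape:
            raise ValueError("candidate shapes differ")
    return np.mean([np.asarray(c, dtype=np.float64) for c in candidates], axis=0)
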