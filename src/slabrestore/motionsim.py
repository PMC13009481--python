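"""Periodic motion-artifact simulation by k-space line splicing.

The subject alternates between the original pose and rigid head
rotations (5-degree in-plane rotation, optional 5-degree through-plane
nodding) following a deterministic 7-step pattern whose minimal time
unit is an echo group (EG) of consecutively acquired k-space lines:

1. stay in the original position for ``Ts``;
2. rotate to the left over 2 EG;
3. hold the left position for 5 EG;
4. rotate back over 2 EG;
5. stay in the original position for ``Ts``;
6. mirror steps 2-4 to the right (9 EG);
7. stay in the original position for ``Ts``;

steps 2-7 repeat until k-space is filled.  One period therefore spans
``18 EG`` of displacement plus ``2 Ts`` of rest, giving the closed-form
corruption ratio ``18 EG / (18 EG + 2 Ts)``: 50%, 33%, 20% and 11% for
``Ts`` = 9, 18, 36 and 72 EG.  Lines are filled along a centric
trajectory (center-out), so corrupted lines preferentially hit the
periphery first when motion starts after the initial rest.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .volume import check_volume, rescale01

__all__ = [
    "MotionSchedule",
    "MotionTimeline",
    "build_timeline",
    "corruption_ratio",
    "rotate_volume",
    "centric_order",
    "corrupt",
]

# per-line state codes (which image's k-space supplies the line)
STATE_ORIGINAL, STATE_LEFT, STATE_RIGHT = 0, 1, 2
LABELS = ("original", "rotating", "rotated_left", "rotated_right")


@dataclass(frozen=True)
class MotionSchedule:
    """Periodic motion pattern in echo-group units.

    Parameters
    ----------
    ts_in_eg : int
        Stationary interval ``Ts`` between motion events, in EG units.
    eg : int
        Echoes (k-space lines) per echo group.
    angle_inplane_deg, angle_throughplane_deg : float
        Rotation angles of the displaced poses.
    trajectory : str
        k-space filling order; only ``"centric"`` is implemented.
    """

    ts_in_eg: int = 9
    eg: int = 80
    angle_inplane_deg: float = 5.0
    angle_throughplane_deg: float = 0.0
    trajectory: str = "centric"

    def __post_init__(self):
        if self.ts_in_eg < 1:
            raise ValueError("Ts must be at least 1 EG")
        if self.eg < 1:
            raise ValueError("EG must contain at least one echo")
        if self.trajectory != "centric":
            raise ValueError(f"unsupported trajectory {self.trajectory!r}")

    @property
    def period_in_eg(self) -> int:
        """Length of one repetition of steps 2-7, in EG."""
        return 18 + 2 * self.ts_in_eg


@dataclass(frozen=True)
class MotionTimeline:
    """Realized per-line acquisition states for a finite k-space fill."""

    labels: np.ndarray   # index into LABELS, per acquired line
    states: np.ndarray   # STATE_* code per acquired line
    schedule: MotionSchedule

    @property
    def n_lines(self) -> int:
        return self.states.size

    @property
    def displaced_fraction(self) -> float:
        """Finite-fill displaced fraction (includes the initial rest block)."""
        return float(np.mean(self.states != STATE_ORIGINAL))


def corruption_ratio(ms: MotionSchedule) -> float:
    """Displaced-line fraction over one period of steps 2-7: 18EG/(18EG+2Ts)."""
    return 18.0 / ms.period_in_eg


def _period_eg_codes(ts: int):
    """(label, state) per EG for one repetition of steps 2-7."""
    rot, left, right, orig = 1, 2, 3, 0
    seq = []
    seq += [(rot, STATE_LEFT)] * 2 + [(left, STATE_LEFT)] * 5 + [(rot, STATE_LEFT)] * 2
    seq += [(orig, STATE_ORIGINAL)] * ts
    seq += [(rot, STATE_RIGHT)] * 2 + [(right, STATE_RIGHT)] * 5 + [(rot, STATE_RIGHT)] * 2
    seq += [(orig, STATE_ORIGINAL)] * ts
    return seq


def build_timeline(ms: MotionSchedule, n_lines: int) -> MotionTimeline:
    """Materialize per-line states for ``n_lines`` acquired k-space lines.

    The timeline starts with the initial ``Ts`` rest block (step 1) and
    then repeats steps 2-7 until ``n_lines`` lines are covered.  The
    2-EG rotation ramps are modeled at the full displaced angle (they
    count as displaced and use the rotated image's k-space).
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    head = [(0, STATE_ORIGINAL)] * ms.ts_in_eg
    period = _period_eg_codes(ms.ts_in_eg)
    n_eg = -(-n_lines // ms.eg)  # ceil
    codes = list(head)
    while len(codes) < n_eg:
        codes += period
    labels_eg = np.array([c[0] for c in codes[:n_eg]], dtype=np.int8)
    states_eg = np.array([c[1] for c in codes[:n_eg]], dtype=np.int8)
    labels = np.repeat(labels_eg, ms.eg)[:n_lines]
    states = np.repeat(states_eg, ms.eg)[:n_lines]
    return MotionTimeline(labels=labels, states=states, schedule=ms)


def centric_order(n: int) -> np.ndarray:
    """Center-out acquisition order of ``n`` phase-encode lines.

    Lines are ordered by ascending distance from the center line
    (index ``n // 2``, the DC line of a DC-centered spectrum), ties
    broken toward the lower index.
    """
    if n < 1:
        raise ValueError("need at least one line")
    idx = np.arange(n)
    dist = np.abs(idx - n // 2)
    return idx[np.lexsort((idx, dist))]


def rotate_volume(volume: np.ndarray, angle_deg: float, axis: str = "inplane",
                  slice_axis: int = 1) -> np.ndarray:
    """Rigidly rotate a volume about its center with trilinear resampling.

    ``axis="inplane"`` rotates within the acquisition plane (the plane
    perpendicular to ``slice_axis``); ``axis="throughplane"`` is a
    nodding rotation mixing the slice axis with the last in-plane axis.
    Out-of-field voxels are filled with 0.
    """
    volume = check_volume(volume)
    if abs(angle_deg) > 30:
        raise ValueError("rotation angle beyond the 30-degree sanity bound")
    if angle_deg == 0:
        return volume.copy()
    inplane = tuple(a for a in range(3) if a != slice_axis)
    if axis == "inplane":
        axes = inplane
    elif axis == "throughplane":
        axes = (slice_axis, inplane[-1])
    else:
        raise ValueError(f"unknown rotation axis {axis!r}")
    return ndimage.rotate(volume, angle_deg, axes=axes, reshape=False,
                          order=1, mode="constant", cval=0.0)


def _rotated_states(volume: np.ndarray, ms: MotionSchedule, slice_axis: int):
    """Precompute one image per distinct pose: original, left, right."""
    def pose(sign: float) -> np.ndarray:
        out = rotate_volume(volume, sign * ms.angle_inplane_deg, "inplane", slice_axis)
        if ms.angle_throughplane_deg:
            out = rotate_volume(out, sign * ms.angle_throughplane_deg,
                                "throughplane", slice_axis)
        return out

    return [volume, pose(+1.0), pose(-1.0)]


def corrupt(volume: np.ndarray, ms: MotionSchedule, slice_axis: int = 1,
            timeline_mode: str = "continuous") -> np.ndarray:
    """Splice k-space lines of rotated poses into the original k-space.

    Per acquisition-plane slice, the 2D spectra of the original and of
    each rotated pose are computed; phase-encode lines are acquired in
    centric order, and each line is copied from the spectrum of the pose
    active at its acquisition time.  With ``timeline_mode="continuous"``
    (default) the timeline advances across slices as in a 3D
    acquisition; ``"per-slice"`` restarts it for every slice.  The
    magnitude of the inverse FFT, rescaled to [0, 1], is returned.
    """
    volume = check_volume(volume)
    if timeline_mode not in ("continuous", "per-slice"):
        raise ValueError(f"unknown timeline mode {timeline_mode!r}")
    inplane = tuple(a for a in range(3) if a != slice_axis)
    line_axis = inplane[-1]          # phase-encode axis within the slice
    n_slices = volume.shape[slice_axis]
    lps = volume.shape[line_axis]    # lines per slice
    total = n_slices * lps if timeline_mode == "continuous" else lps
    timeline = build_timeline(ms, n_lines=total)

    states = _rotated_states(volume, ms, slice_axis)
    spectra = [
        np.fft.fftshift(np.fft.fft2(s, axes=inplane), axes=inplane) for s in states
    ]

    order = centric_order(lps)
    # state code per (slice, line-position-along-line_axis)
    line_state = np.empty((n_slices, lps), dtype=np.int8)
    for si in range(n_slices):
        offset = si * lps if timeline_mode == "continuous" else 0
        line_state[si, order] = timeline.states[offset:offset + lps]

    out_k = spectra[0].copy()
    # broadcast the (slice, line) state map to the full spectrum shape
    expand = [None, None, None]
    expand[slice_axis] = slice(None)
    expand[line_axis] = slice(None)
    state_map = line_state if slice_axis < line_axis else line_state.T
    state_map = state_map[tuple(expand)]
    for code in (STATE_LEFT, STATE_RIGHT):
        mask = np.broadcast_to(state_map == code, out_k.shape)
        out_k[mask] = spectra[code][mask]

    img = np.abs(np.fft.ifft2(np.fft.ifftshift(out_k, axes=inplane), axes=inplane))
    return rescale01(img)


def timeline_summary(ms: MotionSchedule, n_lines: int) -> dict:
    """JSON-ready description of a realized timeline."""
    tl = build_timeline(ms, n_lines)
    counts = {LABELS[i]: int(np.sum(tl.labels == i)) for i in range(len(LABELS))}
    return {
        "ts_in_eg": ms.ts_in_eg,
        "eg": ms.eg,
        "n_lines": n_lines,
        "period_in_eg": ms.period_in_eg,
        "corruption_ratio_periodic": corruption_ratio(ms),
        "corruption_ratio_finite_fill": tl.displaced_fraction,
        "line_counts": counts,
    }
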