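"""3D magnitude-volume conventions and NIfTI I/O.

A *Volume* throughout this package is a real-valued 3D ``numpy.ndarray``
whose axes are ordered (FE, PE, SL) — frequency-encoding, phase-encoding,
slice-encoding — with intensities rescaled to the unit interval.  Plane
semantics follow a sagittally acquired brain volume:

* ``sagittal``  — in-plane axes (FE, PE), through-plane axis SL (axis 2)
* ``axial``     — in-plane axes (FE, SL), through-plane axis PE (axis 1)
"""

from __future__ import annotations

import numpy as np
import nibabel as nib

#: through-plane (slab stacking) axis for each evaluation plane
PLANE_AXIS = {"sagittal": 2, "axial": 1}


def rescale01(volume: np.ndarray) -> np.ndarray:
    """Affinely map intensities to [0, 1].

    A constant volume maps to all zeros (the degenerate case of a
    zero dynamic range is resolved toward the background value).
    """
    volume = np.asarray(volume, dtype=np.float64)
    lo = volume.min()
    hi = volume.max()
    if hi == lo:
        return np.zeros_like(volume)
    return (volume - lo) / (hi - lo)


def check_volume(volume: np.ndarray, name: str = "volume") -> np.ndarray:
    """Validate a 3D finite array and return it as float64."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 3:
        raise ValueError(f"{name} must be 3D (FE, PE, SL); got ndim={volume.ndim}")
    if not np.all(np.isfinite(volume)):
        raise ValueError(f"{name} contains non-finite values")
    return volume


def plane_axis(plane: str) -> int:
    if plane not in PLANE_AXIS:
        raise ValueError(f"unknown plane {plane!r}; expected one of {sorted(PLANE_AXIS)}")
    return PLANE_AXIS[plane]


def save_nifti(volume: np.ndarray, path: str, voxel_size=(1.0, 1.0, 1.0)) -> None:
    """Write a volume as NIfTI with voxel sizes in the header (mm)."""
    volume = check_volume(volume)
    affine = np.diag(list(voxel_size) + [1.0])
    img = nib.Nifti1Image(volume.astype(np.float32), affine)
    img.header.set_zooms(voxel_size)
    nib.save(img, path)


def load_nifti(path: str, rescale: bool = True) -> np.ndarray:
    """Read a NIfTI volume; by default rescale intensities to [0, 1]."""
    data = np.asanyarray(nib.load(path).dataobj).astype(np.float64)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    data = check_volume(data, name=path)
    return rescale01(data) if rescale else data
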