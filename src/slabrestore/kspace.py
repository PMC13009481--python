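"""Frequency-domain degradation for retrospective low-resolution MRI.

A high-resolution volume is taken to k-space with a 3D FFT (DC-centered),
the spectrum is truncated to the central block along each axis according
to an integer scale-factor triple ordered FE x PE x SL, and the inverse
FFT of the retained block yields the low-resolution volume, rescaled to
[0, 1].  Because scan time is driven by phase- and slice-encoding steps,
the acquisition acceleration equals ``s_pe * s_sl``; the fraction of
complex coefficients discarded is ``1 - 1/(s_fe*s_pe*s_sl)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import check_volume, rescale01

__all__ = [
    "ScaleFactor",
    "to_kspace",
    "from_kspace",
    "truncate_central",
    "degrade_lr",
    "acceleration",
    "discarded_fraction",
]

_AXIS_NAMES = ("FE", "PE", "SL")


@dataclass(frozen=True)
class ScaleFactor:
    """Integer down-sampling triple ordered FE x PE x SL."""

    s_fe: int = 1
    s_pe: int = 1
    s_sl: int = 1

    def __post_init__(self):
        for name, s in zip(_AXIS_NAMES, self):
            if int(s) < 1 or int(s) != s:
                raise ValueError(f"scale factor along {name} must be a positive integer; got {s}")

    def __iter__(self):
        return iter((self.s_fe, self.s_pe, self.s_sl))

    @classmethod
    def parse(cls, text) -> "ScaleFactor":
        """Accept a ScaleFactor, an (fe, pe, sl) triple, or 'fe,pe,sl' text."""
        if isinstance(text, cls):
            return text
        if isinstance(text, str):
            parts = [int(p) for p in text.replace("x", ",").split(",")]
        else:
            parts = [int(p) for p in text]
        if len(parts) != 3:
            raise ValueError(f"scale factor needs 3 components (FE,PE,SL); got {text!r}")
        return cls(*parts)

    def check_divides(self, shape) -> None:
        for name, s, n in zip(_AXIS_NAMES, self, shape):
            if n % s != 0:
                raise ValueError(
                    f"scale factor {s} does not divide the {name} dimension ({n})"
                )


def acceleration(sf: ScaleFactor) -> int:
    """Scan-time acceleration: product of PE and SL sub-sampling ratios."""
    sf = ScaleFactor.parse(sf)
    return sf.s_pe * sf.s_sl


def discarded_fraction(sf: ScaleFactor) -> float:
    """Fraction of complex k-space coefficients removed by central truncation."""
    sf = ScaleFactor.parse(sf)
    return 1.0 - 1.0 / (sf.s_fe * sf.s_pe * sf.s_sl)


def to_kspace(volume: np.ndarray) -> np.ndarray:
    """3D FFT with the DC component shifted to the array center."""
    volume = check_volume(volume)
    return np.fft.fftshift(np.fft.fftn(volume))


def from_kspace(spectrum: np.ndarray, imag_tol: float | None = 1e-8) -> np.ndarray:
    """Inverse of :func:`to_kspace`, returning the real part.

    For a full spectrum of a real volume the inverse is real to machine
    precision and a residue above ``imag_tol`` of the signal scale
    raises.  A centrally truncated spectrum of an even-sized grid keeps
    an unpaired Nyquist plane per truncated axis, leaving an imaginary
    residue on the percent scale; taking the real part is exactly the
    inverse of the Hermitian-symmetrized spectrum and discards only that
    asymmetric component.  Pass ``imag_tol=None`` in that case.
    """
    img = np.fft.ifftn(np.fft.ifftshift(np.asarray(spectrum)))
    scale = np.max(np.abs(img))
    if imag_tol is not None and scale > 0 and np.max(np.abs(img.imag)) > imag_tol * scale:
        raise ValueError("inverse FFT produced a non-negligible imaginary part")
    return np.ascontiguousarray(img.real)


def _central_slices(shape, sf: ScaleFactor):
    # centered block of size n/s per axis: [n/2 - n/(2s), n/2 + n/(2s))
    slices = []
    for n, s in zip(shape, sf):
        m = n // s
        start = n // 2 - m // 2
        slices.append(slice(start, start + m))
    return tuple(slices)


def truncate_central(spectrum: np.ndarray, sf: ScaleFactor, keep_matrix: bool = False) -> np.ndarray:
    """Retain the central (dim/s) block of a DC-centered spectrum.

    With ``keep_matrix=True`` the discarded coefficients are zero-filled so
    the matrix size is preserved (low-resolution content on the original
    voxel grid); with ``keep_matrix=False`` the retained block itself is
    returned (the true low-resolution acquisition, with proportionally
    larger voxels).
    """
    spectrum = np.asarray(spectrum)
    sf = ScaleFactor.parse(sf)
    sf.check_divides(spectrum.shape)
    block = _central_slices(spectrum.shape, sf)
    if keep_matrix:
        out = np.zeros_like(spectrum)
        out[block] = spectrum[block]
        return out
    return np.ascontiguousarray(spectrum[block])


def degrade_lr(volume: np.ndarray, sf: ScaleFactor, keep_matrix: bool = False) -> np.ndarray:
    """Simulate a low-resolution acquisition of ``volume``.

    FFT -> central truncation -> inverse FFT -> rescale to [0, 1].  The
    output shape is the input shape divided componentwise by the scale
    factor (or the input shape when ``keep_matrix=True``).
    """
    sf = ScaleFactor.parse(sf)
    spectrum = to_kspace(volume)
    truncated = truncate_central(spectrum, sf, keep_matrix=keep_matrix)
    return rescale01(from_kspace(truncated, imag_tol=None))
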