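"""Centred Fourier-grid conventions shared by the simulator and corrector.

All 2D/3D transforms in this package use a "centred" layout: the zero
frequency sits at index N/2 on every axis (numpy's fftshift layout), and the
real-space origin is the box centre.  Frequencies are integer lattice points
k in [-N/2, N/2) per axis, converted to physical units as s = k/(N*pixel).

For even N the row/plane at k = -N/2 has no Friedel partner inside the grid;
every transfer operation here therefore acts only inside the open Nyquist
disc |s| < 1/(2*pixel) and zeroes the rest, so unit-modulus complex
multipliers can preserve Hermitian symmetry exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def centered_fft2(image: np.ndarray) -> np.ndarray:
    """2D FFT with the real-space origin at the box centre, centred output."""
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(image)))


def centered_ifft2(ft: np.ndarray) -> np.ndarray:
    """Inverse of :func:`centered_fft2` (complex output; take .real as needed)."""
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(ft)))


def centered_fftn(vol: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol)))


def centered_ifftn(ft: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(ft)))


def freq_grid(n: int, pixel_size: float):
    """Centred frequency coordinates for an n x n image.

    Returns (sx, sy, s_mag, azimuth): each n x n, in 1/A (azimuth in
    radians, atan2(sy, sx)).  Axis 0 of the array is x, axis 1 is y.
    """
    k = np.arange(n) - n // 2
    step = 1.0 / (n * pixel_size)
    sx = (k * step)[:, None] * np.ones((1, n))
    sy = np.ones((n, 1)) * (k * step)[None, :]
    s_mag = np.hypot(sx, sy)
    azimuth = np.arctan2(sy, sx)
    return sx, sy, s_mag, azimuth


def nyquist_disc(n: int) -> np.ndarray:
    """Boolean mask of centred integer frequencies with |k| < N/2."""
    k = np.arange(n) - n // 2
    kx = k[:, None]
    ky = k[None, :]
    return kx * kx + ky * ky < (n // 2) ** 2


def hermitian_mate(ft: np.ndarray) -> np.ndarray:
    """conj(F(-s)) on a centred grid; index-0 rows/planes are zeroed.

    For a Hermitian transform this equals the input inside the Nyquist disc.
    Works for 2D and 3D arrays.
    """
    flipped = np.conj(ft[(slice(None, None, -1),) * ft.ndim])
    rolled = np.roll(flipped, shift=(1,) * ft.ndim, axis=tuple(range(ft.ndim)))
    for ax in range(ft.ndim):
        sl = [slice(None)] * ft.ndim
        sl[ax] = 0
        rolled[tuple(sl)] = 0.0
    return rolled


def hermitianize(ft: np.ndarray) -> np.ndarray:
    """Project a centred transform onto its Hermitian part."""
    out = 0.5 * (ft + hermitian_mate(ft))
    # the index-0 rows/planes have no partner; drop them (beyond Nyquist disc)
    for ax in range(ft.ndim):
        sl = [slice(None)] * ft.ndim
        sl[ax] = 0
        out[tuple(sl)] = 0.0
    return out


@dataclass
class FourierImage:
    """Square 2D complex transform with pixel size, centred layout.

    ``values[i, j]`` holds frequency (i - N/2, j - N/2) in integer lattice
    units; physical frequency is k/(N*pixel_size).  When the transform
    represents a real image it is Hermitian: value(-s) = conj(value(s)).
    """

    values: np.ndarray
    pixel_size: float
    origin_convention: str = "centered"

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"expected a square 2D array, got shape {v.shape}")
        if v.shape[0] % 2 != 0:
            raise ValueError("image size must be even")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.origin_convention != "centered":
            raise ValueError(f"unknown origin convention {self.origin_convention!r}")
        self.values = np.asarray(v, dtype=complex)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @classmethod
    def from_real_image(cls, image: np.ndarray, pixel_size: float) -> "FourierImage":
        return cls(centered_fft2(np.asarray(image, dtype=float)), pixel_size)

    def to_real_image(self) -> np.ndarray:
        return centered_ifft2(self.values).real

    def hermitian_error(self) -> float:
        """Relative deviation from Hermitian symmetry inside the Nyquist disc."""
        disc = nyquist_disc(self.n)
        diff = np.abs(self.values - hermitian_mate(self.values))[disc]
        scale = np.abs(self.values[disc]).max()
        if scale == 0:
            return 0.0
        return float(diff.max() / scale)

    def is_hermitian(self, tol: float = 1e-10) -> bool:
        return self.hermitian_error() <= tol
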