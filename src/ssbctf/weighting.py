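"""Sideband-overlap fraction A and the 3D insertion weight W.

The overlap fraction is the common area of the two sideband discs (each of
particle diameter D, centres 2*dF*lambda/d apart) divided by the disc area:

    A(u) = (2/pi) * (arccos u - u * sqrt(1 - u^2)),   u = 2 dF lambda / (d D)

for u < 1 and 0 beyond.  The insertion weight is W = 1 + A (2|sin chi| - 1):
|CTFR| where the sidebands fully overlap, exactly 1 where they are separate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class OverlapInput:
    """Parameters controlling sideband overlap for one Fourier spacing."""

    defocus: float  # dF, Angstrom
    resolution: float  # d, Angstrom
    particle_diameter: float  # D, Angstrom
    wavelength: float  # lambda, Angstrom

    def __post_init__(self) -> None:
        for name in ("resolution", "particle_diameter", "wavelength"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.defocus < 0:
            raise ValueError("defocus must be non-negative")

    @property
    def u(self) -> float:
        """Centre separation in units of the disc diameter."""
        return 2.0 * self.defocus * self.wavelength / (
            self.resolution * self.particle_diameter
        )


def overlap_area_fraction(u):
    """Fractional common area of two unit-diameter discs at centre distance u.

    Continuous on [0, inf): 1 at u = 0, 0 for u >= 1 (the u = 1 boundary is a
    removable point where both branches vanish).  Accepts scalars or arrays.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0):
        raise ValueError("centre distance must be non-negative")
    uc = np.clip(u_arr, 0.0, 1.0)
    frac = (2.0 / np.pi) * (np.arccos(uc) - uc * np.sqrt(1.0 - uc * uc))
    frac = np.where(u_arr >= 1.0, 0.0, frac)
    return float(frac) if np.isscalar(u) else frac


def overlap_fraction(inp: OverlapInput):
    """Overlap fraction A for given defocus, spacing, diameter and wavelength."""
    return overlap_area_fraction(inp.u)


def insertion_weight(chi_val, overlap):
    """Insertion weight W = 1 + A (2|sin chi| - 1).

    Lies between min(1, 2|sin chi|) and max(1, 2|sin chi|); equals the
    magnitude of the conventional CTF at full overlap and 1 at none.
    """
    a = np.asarray(overlap, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise ValueError("overlap fraction must lie in [0, 1]")
    w = 1.0 + a * (2.0 * np.abs(np.sin(np.asarray(chi_val, dtype=float))) - 1.0)
    if np.isscalar(chi_val) and np.isscalar(overlap):
        return float(w)
    return w


def disc_overlap_oracle(u: float, n_samples: int = 200_000, seed: int = 0):
    """Monte-Carlo estimate of the disc-overlap fraction, with standard error.

    Samples points uniformly in one unit-diameter disc and counts the
    fraction falling inside a second disc whose centre is a distance ``u``
    away.  Returns (estimate, standard_error).  Independent of the closed
    form; used to verify it.
    """
    if u < 0:
        raise ValueError("centre distance must be non-negative")
    if n_samples < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    r = 0.5 * np.sqrt(rng.random(n_samples))  # radius CDF ~ r^2
    phi = rng.random(n_samples) * 2.0 * np.pi
    x = r * np.cos(phi)
    y = r * np.sin(phi)
    inside = (x - u) ** 2 + y**2 <= 0.25
    p = inside.mean()
    se = np.sqrt(max(p * (1.0 - p), 1.0 / n_samples) / n_samples)
    return float(p), float(se)
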