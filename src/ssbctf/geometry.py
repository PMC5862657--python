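"""Ewald-sphere geometry: sideband offsets, separations and defocus rules.

All formulas use the small-angle approximation theta = lambda/d.  Units are
Angstrom (and 1/Angstrom) throughout; conversions from um/mm happen only at
the CLI boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .optics import electron_wavelength


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value <= 0:
            raise ValueError(f"{name} must be positive, got {value}")


@dataclass(frozen=True)
class SeparationSpec:
    """Bundle of the quantities governing sideband separation."""

    particle_diameter: float  # D, Angstrom
    resolution: float  # d, Angstrom
    wavelength: float  # lambda, Angstrom
    defocus: float  # dF, Angstrom

    def __post_init__(self) -> None:
        _check_positive(
            particle_diameter=self.particle_diameter,
            resolution=self.resolution,
            wavelength=self.wavelength,
            defocus=self.defocus,
        )


def delta_zstar(resolution: float, wavelength: float) -> float:
    """Ewald-sphere deviation from the central section, lambda/(2 d^2), in 1/A."""
    _check_positive(resolution=resolution, wavelength=wavelength)
    return wavelength / (2.0 * resolution**2)


def sideband_separation(defocus: float, wavelength: float, resolution: float) -> float:
    """In-image distance 2 dF lambda / d between the two sideband centres (A)."""
    _check_positive(wavelength=wavelength, resolution=resolution)
    if defocus < 0:
        raise ValueError("defocus must be non-negative")
    return 2.0 * defocus * wavelength / resolution


def min_defocus(particle_diameter: float, resolution: float, wavelength: float) -> float:
    """Defocus D d / (2 lambda) above which the sidebands fully separate (A).

    At this defocus the two sideband discs of a particle of diameter D just
    touch at spacing d; any finer spacing is separated by more.
    """
    _check_positive(
        particle_diameter=particle_diameter, resolution=resolution, wavelength=wavelength
    )
    return particle_diameter * resolution / (2.0 * wavelength)


def significance_diameter(resolution: float, wavelength: float) -> float:
    """Particle diameter d^2/lambda above which curvature matters at spacing d (A).

    This is the D at which the reciprocal-space sideband separation
    2*delta_zstar equals 1/D, i.e. where the two sideband samples are a full
    particle-transform feature apart along z*.
    """
    _check_positive(resolution=resolution, wavelength=wavelength)
    return resolution**2 / wavelength


def required_box_size(
    particle_diameter: float, defocus: float, wavelength: float, resolution: float
) -> float:
    """Minimum box edge D + 2 dF lambda / d containing particle and sidebands (A)."""
    _check_positive(particle_diameter=particle_diameter)
    return particle_diameter + sideband_separation(defocus, wavelength, resolution)


def geometry_table(
    energies: Sequence[float],
    diameters: Sequence[float],
    resolutions: Sequence[float],
    paper_lambda: bool = False,
) -> pd.DataFrame:
    """Tabulate the minimum separating defocus over a parameter cross product.

    Returns a long-format DataFrame with columns voltage_kev, wavelength_A,
    diameter_A, resolution_A, min_defocus_A, min_defocus_um.  With
    ``paper_lambda`` the rounded literature wavelengths are used where
    tabulated.
    """
    if not energies or not diameters or not resolutions:
        raise ValueError("energies, diameters and resolutions must be non-empty")
    from .optics import ROUNDED_WAVELENGTHS

    rows = []
    for kev in energies:
        lam = electron_wavelength(kev)
        if paper_lambda:
            lam = ROUNDED_WAVELENGTHS.get(float(kev), lam)
        for d_particle in diameters:
            for res in resolutions:
                df_min = min_defocus(d_particle, res, lam)
                rows.append(
                    {
                        "voltage_kev": kev,
                        "wavelength_A": lam,
                        "diameter_A": d_particle,
                        "resolution_A": res,
                        "min_defocus_A": df_min,
                        "min_defocus_um": df_min * 1e-4,
                    }
                )
    return pd.DataFrame(rows)


def plot_geometry_table(table: pd.DataFrame, path: str) -> None:
    """Write defocus-requirement curves (defocus vs diameter per energy)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for (kev, res), grp in table.groupby(["voltage_kev", "resolution_A"]):
        grp = grp.sort_values("diameter_A")
        ax.plot(
            grp["diameter_A"],
            grp["min_defocus_um"],
            marker="o",
            label=f"{kev:g} keV, d={res:g} A",
        )
    ax.set_xlabel("particle diameter D (A)")
    ax.set_ylabel("minimum defocus (um)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
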