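"""Scalar contrast-transfer optics.

Electron wavelength, the aberration phase chi, and the real and complex
contrast transfer functions used throughout the package.

Sign conventions
----------------
chi(s) = -(2*pi/lambda) * (dF*theta^2/2 - Cs*theta^4/4), theta = lambda*s.

Positive defocus ``dF`` means *underfocus* (objective focused below the
specimen).  With this sign, chi < 0 at low resolution for an underfocused
image and the conventional transfer function CTFR = -2 sin(chi) gives
positive low-resolution contrast, which is the convention used for all
internal math.  Figure-style displays elsewhere often print underfocus as a
negative number; that is a display convention only.

Amplitude contrast is folded into the phase of the single-sideband transfer
functions as CTFP = exp(+i(chi + pi/2 - arcsin(W))) so that
CTFP + CTFQ = 2*(W*cos(chi) - sqrt(1-W^2)*sin(chi)) holds to machine
precision.  The total phase shift on scattering, quoted in the
underfocus-positive convention common to CTF-estimation software, is
90 deg + arcsin(W) (about 94 deg for W = 0.07 at 100 keV); see
``OpticalModel.scattering_phase_deg``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

# CODATA 2018 constants (SI)
_PLANCK = 6.62607015e-34
_M0 = 9.1093837015e-31
_E_CHARGE = 1.602176634e-19
_C_LIGHT = 299792458.0

#: Rounded wavelengths printed in the source literature, keyed by keV.
ROUNDED_WAVELENGTHS = {300.0: 0.02, 100.0: 0.037}

#: Typical amplitude-contrast fractions by accelerating voltage (keV).
DEFAULT_AMP_CONTRAST = {300.0: 0.04, 100.0: 0.07}


def electron_wavelength(voltage_kev: float) -> float:
    """Relativistic electron wavelength in Angstrom for a voltage in keV.

    lambda = h / sqrt(2 m0 e V (1 + e V / (2 m0 c^2)))
    """
    if voltage_kev <= 0:
        raise ValueError(f"voltage must be positive, got {voltage_kev} keV")
    v = float(voltage_kev) * 1e3
    lam_m = _PLANCK / math.sqrt(
        2.0 * _M0 * _E_CHARGE * v * (1.0 + _E_CHARGE * v / (2.0 * _M0 * _C_LIGHT**2))
    )
    return lam_m * 1e10


def voltage_for_wavelength(wavelength: float) -> float:
    """Accelerating voltage (keV) whose relativistic wavelength is given (A).

    Inverse of :func:`electron_wavelength`; useful for constructing
    self-consistent models at scaled wavelengths.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    lam_m = wavelength * 1e-10
    ev = _C_LIGHT**2 * (
        -_M0 + math.sqrt(_M0**2 + (_PLANCK / (lam_m * _C_LIGHT)) ** 2)
    ) / _E_CHARGE
    return ev / 1e3


@dataclass
class OpticalModel:
    """Everything the aberration phase needs, in Angstrom and radians.

    Parameters
    ----------
    voltage_kev
        Accelerating voltage in keV.
    defocus
        Defocus dF in Angstrom; positive = underfocus.
    cs
        Third-order spherical aberration coefficient in Angstrom
        (1 mm = 1e7 A).
    amp_contrast
        Amplitude-contrast fraction W, 0 <= W < 1.
    extra_phase
        Constant additional phase in radians (e.g. a phase plate).
    astig_amount
        Defocus difference dF_max - dF_min in Angstrom (two-fold
        astigmatism); 0 disables it.
    astig_angle
        Azimuth of the astigmatism major axis, radians.
    wavelength
        Electron wavelength in Angstrom.  Computed relativistically from
        ``voltage_kev`` when omitted; an explicit value (e.g. the rounded
        0.02 A used in worked examples) must agree with the relativistic
        one within 1 %.
    paper_lambda
        When True, use the rounded literature wavelength for the voltage
        (0.02 A at 300 keV, 0.037 A at 100 keV) so printed numbers
        reproduce exactly.
    """

    voltage_kev: float
    defocus: float
    cs: float = 0.0
    amp_contrast: float = 0.0
    extra_phase: float = 0.0
    astig_amount: float = 0.0
    astig_angle: float = 0.0
    wavelength: float | None = None
    paper_lambda: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.amp_contrast < 1.0:
            raise ValueError(f"amp_contrast must be in [0, 1), got {self.amp_contrast}")
        exact = electron_wavelength(self.voltage_kev)
        if self.wavelength is None:
            if self.paper_lambda:
                try:
                    self.wavelength = ROUNDED_WAVELENGTHS[float(self.voltage_kev)]
                except KeyError:
                    raise ValueError(
                        f"no rounded wavelength tabulated for {self.voltage_kev} keV"
                    ) from None
            else:
                self.wavelength = exact
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not self.paper_lambda and abs(self.wavelength - exact) > 0.01 * exact:
            raise ValueError(
                f"wavelength {self.wavelength} A inconsistent with "
                f"{self.voltage_kev} keV (relativistic value {exact:.5f} A)"
            )

    @property
    def scattering_phase_deg(self) -> float:
        """Total phase shift on scattering including amplitude contrast.

        90 deg from the weak-phase approximation plus arcsin(W), quoted in
        the underfocus-positive sign convention (about 94 deg at W = 0.07).
        """
        return 90.0 + math.degrees(math.asin(self.amp_contrast))


def chi(spatial_freq, azimuth, model: OpticalModel):
    """Aberration phase chi in radians at spatial frequency s (1/A).

    theta = lambda * s; with astigmatism the defocus becomes
    dF + (astig_amount/2) * cos 2(azimuth - astig_angle).  ``extra_phase``
    is added unconditionally.  Accepts scalars or arrays.
    """
    s = np.asarray(spatial_freq, dtype=float)
    if np.any(s < 0):
        raise ValueError("spatial frequency must be non-negative")
    lam = model.wavelength
    theta2 = (lam * s) ** 2
    dz = model.defocus
    if model.astig_amount:
        az = np.asarray(azimuth, dtype=float)
        dz = dz + 0.5 * model.astig_amount * np.cos(2.0 * (az - model.astig_angle))
    out = -(2.0 * np.pi / lam) * (dz * theta2 / 2.0 - model.cs * theta2**2 / 4.0)
    out = out + model.extra_phase
    if np.isscalar(spatial_freq) and np.isscalar(azimuth):
        return float(out)
    return out


def _phase_offset(model: OpticalModel) -> float:
    # pi/2 scattering phase, reduced by arcsin(W) in this chi convention so
    # that CTFP + CTFQ reproduces W cos(chi) - sqrt(1 - W^2) sin(chi).
    return 0.5 * np.pi - math.asin(model.amp_contrast)


def ctf_p(chi_val, model: OpticalModel):
    """Single-sideband transfer CTFP = exp(+i(chi + pi/2 - arcsin W))."""
    return np.exp(1j * (np.asarray(chi_val, dtype=float) + _phase_offset(model)))


def ctf_q(chi_val, model: OpticalModel):
    """Single-sideband transfer CTFQ = conj(CTFP); unit modulus."""
    return np.exp(-1j * (np.asarray(chi_val, dtype=float) + _phase_offset(model)))


def ctf_r(chi_val, model: OpticalModel):
    """Conventional real transfer function CTFR = CTFP + CTFQ.

    Equals -2 sin(chi) for W = 0 and
    2 (W cos(chi) - sqrt(1 - W^2) sin(chi)) in general.
    """
    c = np.asarray(chi_val, dtype=float)
    w = model.amp_contrast
    return 2.0 * (w * np.cos(c) - math.sqrt(1.0 - w * w) * np.sin(c))
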