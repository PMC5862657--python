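"""Synthetic weak-phase data with a curved-Ewald forward imaging model.

The forward model samples the phantom's 3D transform twice per image
frequency, once on each side of the central section:

    I_hat(s) = CTFP(s) * F(R (s, +dz*)) + CTFQ(s) * F(R (s, -dz*)),

with dz* = lambda |s|^2 / 2 and R the particle orientation.  Both transfer
factors have unit modulus, and the pairing of conjugate factors with
mirrored z* offsets makes I_hat Hermitian, hence the image real.  Forcing
dz* to zero collapses both samples onto the central section and the model
reduces exactly to the conventional weak-phase image CTFR x projection.

Also here: the classic single-fringe demonstration image (one Fourier
component of a small particle, delocalised by defocus), reproducible white
noise, and a chiral (mirror-asymmetric) phantom for hand validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from .fourier import (
    centered_fft2,
    centered_fftn,
    centered_ifft2,
    freq_grid,
    hermitianize,
    nyquist_disc,
)
from .geometry import required_box_size
from .optics import OpticalModel, chi, ctf_p, ctf_q


@dataclass
class Phantom3D:
    """Real 3D density on an N^3 grid, centred in the box.

    The oversampled (zero-padded) centred transform used for off-section
    sampling is computed lazily and cached.
    """

    values: np.ndarray
    pixel_size: float
    chirality_tag: str = ""
    oversample: int = 2
    _ft_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or len(set(v.shape)) != 1:
            raise ValueError("phantom must be a cubic 3D array")
        if v.shape[0] % 2 != 0:
            raise ValueError("phantom size must be even")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def oversampled_ft(self) -> np.ndarray:
        if self._ft_cache is None:
            n, m = self.n, self.oversample * self.n
            pad = (m - n) // 2
            vol = np.zeros((m, m, m))
            vol[pad : pad + n, pad : pad + n, pad : pad + n] = self.values
            self._ft_cache = centered_fftn(vol)
        return self._ft_cache

    def mirrored(self) -> "Phantom3D":
        """Mirror image through the box-centre xy plane (z flip)."""
        flipped = np.roll(self.values[:, :, ::-1], 1, axis=2)
        return Phantom3D(
            flipped, self.pixel_size, chirality_tag=f"mirror({self.chirality_tag})",
            oversample=self.oversample,
        )

    def mirror_correlation(self) -> float:
        a = self.values.ravel()
        b = self.mirrored().values.ravel()
        return float(np.corrcoef(a, b)[0, 1])


def _sample_ft(ft_os: np.ndarray, coords_recip: np.ndarray, box_size: float) -> np.ndarray:
    """Trilinear sample of a centred oversampled 3D transform.

    ``coords_recip``: (3, M) reciprocal coordinates in 1/A; ``box_size`` is
    the *oversampled* box edge in A (so one voxel = 1/box_size).
    """
    m = ft_os.shape[0]
    vox = coords_recip * box_size + m // 2
    re = map_coordinates(ft_os.real, vox, order=1, mode="constant", cval=0.0)
    im = map_coordinates(ft_os.imag, vox, order=1, mode="constant", cval=0.0)
    return re + 1j * im


def _curvature_factor(curvature: str) -> float:
    try:
        return {"on": 1.0, "off": 0.0, "inverted": -1.0}[curvature]
    except KeyError:
        raise ValueError(
            f"curvature must be 'on', 'off' or 'inverted', got {curvature!r}"
        ) from None


def _check_rotation(rot: np.ndarray) -> np.ndarray:
    r = np.asarray(rot, dtype=float)
    if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-8) or (
        np.linalg.det(r) < 0
    ):
        raise ValueError("orientation must be a proper rotation matrix")
    return r


def forward_image(
    phantom: Phantom3D,
    orientation: np.ndarray,
    model: OpticalModel,
    curvature: str = "on",
    image_size: int | None = None,
) -> np.ndarray:
    """Simulate one weak-phase particle image with optional Ewald curvature.

    ``curvature``: 'on' (dz* as physics dictates), 'off' (flat sphere,
    conventional CTFR x projection exactly) or 'inverted' (dz* negated).
    Output is a real image at the phantom's pixel size; ``image_size``
    (default: the phantom size) should satisfy the box rule
    D + 2 dF lambda / d so delocalised fringes do not wrap into the mask.
    """
    r = _check_rotation(orientation)
    factor = _curvature_factor(curvature)
    n, px = image_size or phantom.n, phantom.pixel_size
    ft_os = phantom.oversampled_ft()
    box_os = phantom.oversample * phantom.n * px

    sx, sy, s_mag, azimuth = freq_grid(n, px)
    disc = nyquist_disc(n)
    dz = factor * 0.5 * model.wavelength * s_mag**2

    flat = disc.ravel()
    plane = np.stack([sx.ravel()[flat], sy.ravel()[flat], np.zeros(flat.sum())])
    offs = dz.ravel()[flat]

    def branch(sign: float) -> np.ndarray:
        pts = plane.copy()
        pts[2] = sign * offs
        vals = np.zeros(n * n, dtype=complex)
        vals[flat] = _sample_ft(ft_os, r @ pts, box_os)
        return vals.reshape(n, n)

    chi_grid = chi(s_mag, azimuth, model)
    i_hat = ctf_p(chi_grid, model) * branch(+1.0) + ctf_q(chi_grid, model) * branch(-1.0)
    i_hat[~disc] = 0.0
    i_hat = hermitianize(i_hat)
    # the DC term carries no phase contrast; each sideband pass carries it
    # through untouched, so the pair convention gives it weight 2
    i_hat[n // 2, n // 2] = 2.0 * _sample_ft(ft_os, np.zeros((3, 1)), box_os)[0].real
    return centered_ifft2(i_hat).real


def project(
    phantom: Phantom3D, orientation: np.ndarray, image_size: int | None = None
) -> np.ndarray:
    """Projection along the beam via the central Fourier slice.

    Uses the same oversampled trilinear sampling as :func:`forward_image`,
    so the flat-sphere degeneracy `forward = CTFR x projection` is exact.
    """
    r = _check_rotation(orientation)
    n, px = image_size or phantom.n, phantom.pixel_size
    ft_os = phantom.oversampled_ft()
    box_os = phantom.oversample * phantom.n * px
    sx, sy, _, _ = freq_grid(n, px)
    disc = nyquist_disc(n)
    flat = disc.ravel()
    pts = np.stack([sx.ravel()[flat], sy.ravel()[flat], np.zeros(flat.sum())])
    vals = np.zeros(n * n, dtype=complex)
    vals[flat] = _sample_ft(ft_os, r @ pts, box_os)
    slice_ft = vals.reshape(n, n)
    slice_ft[n // 2, n // 2] = _sample_ft(ft_os, np.zeros((3, 1)), box_os)[0].real
    slice_ft = hermitianize(slice_ft)
    slice_ft[n // 2, n // 2] = slice_ft[n // 2, n // 2].real
    return centered_ifft2(slice_ft).real


@dataclass(frozen=True)
class SingleComponentSpec:
    """A particle diffracting a single Fourier component in one direction."""

    particle_diameter: float  # D, Angstrom
    fringe_resolution: float  # d, Angstrom
    fringe_azimuth: float = 0.0  # radians
    amplitude: float = 1.0
    fringe_phase: float = 0.0  # radians
    shadow_depth: float = 0.5  # depth of the low-frequency particle shadow


def single_component_image(
    spec: SingleComponentSpec,
    model: OpticalModel,
    image_size: int,
    pixel_size: float = 1.0,
) -> np.ndarray:
    """Noise-free image of a particle with one single-sided Fourier component.

    The component rides the CTFP carrier only (its opposed Bragg partner is
    absent), so the raw image shows a single fringe patch displaced by
    dF*lambda/d from the particle centre, next to a uniform dark shadow disc
    marking the particle.  This is the elementary demonstration of sideband
    delocalisation and of its removal by the complex correction.
    """
    if spec.fringe_resolution < 2.0 * pixel_size:
        raise ValueError(
            f"fringe resolution {spec.fringe_resolution} A violates Nyquist "
            f"at {pixel_size} A/px"
        )
    box = image_size * pixel_size
    need = required_box_size(
        spec.particle_diameter, model.defocus, model.wavelength, spec.fringe_resolution
    )
    if need > box:
        raise ValueError(f"box {box:.0f} A too small; need {need:.0f} A")

    n = image_size
    coords = (np.arange(n) - n // 2) * pixel_size
    x = coords[:, None]
    y = coords[None, :]
    in_disc = np.hypot(x, y) <= spec.particle_diameter / 2.0

    s0 = 1.0 / spec.fringe_resolution
    s0x, s0y = s0 * np.cos(spec.fringe_azimuth), s0 * np.sin(spec.fringe_azimuth)
    carrier = np.exp(1j * (2.0 * np.pi * (s0x * x + s0y * y) + spec.fringe_phase))
    o_plus = in_disc * (0.5 * spec.amplitude) * carrier

    _, _, s_mag, azimuth = freq_grid(n, pixel_size)
    chi_grid = chi(s_mag, azimuth, model)
    f_plus = centered_fft2(o_plus)
    f_minus = centered_fft2(np.conj(o_plus))
    i_hat = ctf_p(chi_grid, model) * f_plus + ctf_q(chi_grid, model) * f_minus
    i_hat[~nyquist_disc(n)] = 0.0
    i_hat = hermitianize(i_hat)
    fringes = centered_ifft2(i_hat).real

    shadow = -spec.shadow_depth * spec.amplitude * in_disc
    return fringes + shadow


def add_noise(image: np.ndarray, noise_sd: float, seed: int) -> np.ndarray:
    """Add reproducible white Gaussian noise; noise_sd = 0 is the identity."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    img = np.asarray(image, dtype=float)
    if noise_sd == 0:
        return img.copy()
    rng = np.random.default_rng(seed)
    return img + rng.normal(0.0, noise_sd, size=img.shape)


def make_chiral_phantom(
    size: int,
    pixel_size: float,
    diameter: float,
    seed: int = 0,
    n_blobs: int = 9,
) -> Phantom3D:
    """Helical arrangement of Gaussian blobs: nonnegative, mirror-asymmetric.

    The helix (1.5 turns, right-handed for the returned chirality tag)
    guarantees low correlation with its own mirror image, so hand tests
    built on this phantom have discriminating power.  Blob amplitudes,
    widths and positions are jittered reproducibly from ``seed``.
    """
    if diameter >= size * pixel_size:
        raise ValueError("phantom diameter must fit inside the box")
    rng = np.random.default_rng(seed)
    t = np.linspace(-1.0, 1.0, n_blobs)
    twist = 1.5 * np.pi  # 1.5 turns over the helix
    helix_r = 0.28 * diameter
    centers = np.stack(
        [
            helix_r * np.cos(twist * t),
            helix_r * np.sin(twist * t),
            0.38 * diameter * t,
        ],
        axis=1,
    )
    centers += rng.normal(0.0, 0.02 * diameter, size=centers.shape)
    sigmas = diameter / 10.0 * rng.uniform(0.8, 1.2, size=n_blobs)
    amps = rng.uniform(0.7, 1.3, size=n_blobs)
    # dominant sharp cores keep the spectrum strong near Nyquist, where the
    # sidebands are fully separated and curvature effects are largest (akin
    # to the strong lattice reflections of a nanocrystal test specimen);
    # the broad component supplies a particle-like envelope
    broad_amp = 0.25
    core_sigma = max(diameter / 22.0, 1.0 * pixel_size)
    core_offsets = rng.normal(0.0, 0.03 * diameter, size=centers.shape)

    coords = (np.arange(size) - size // 2) * pixel_size
    x = coords[:, None, None]
    y = coords[None, :, None]
    z = coords[None, None, :]
    vol = np.zeros((size, size, size))
    for (cx, cy, cz), (ox, oy, oz), sig, amp in zip(centers, core_offsets, sigmas, amps):
        r2 = (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2
        vol += broad_amp * amp * np.exp(-r2 / (2.0 * sig**2))
        r2c = (x - cx - ox) ** 2 + (y - cy - oy) ** 2 + (z - cz - oz) ** 2
        vol += amp * np.exp(-r2c / (2.0 * core_sigma**2))
    # confine support strictly inside the stated diameter
    r = np.sqrt(x**2 + y**2 + z**2)
    edge = 0.05 * diameter
    taper = np.clip((diameter / 2.0 - r) / edge, 0.0, 1.0)
    vol *= taper
    return Phantom3D(vol, pixel_size, chirality_tag=f"right-handed-helix(seed={seed})")
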