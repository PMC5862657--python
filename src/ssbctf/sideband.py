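"""The single-sideband correction algorithm.

A defocused weak-phase image superimposes two displaced copies (sidebands)
of every Fourier fringe, one from each of the two opposed Bragg beams.  The
two beams sample the specimen transform at +dz* and -dz* off the central
section (Ewald curvature), so a conventional real CTF correction mixes two
different 3D Fourier samples.  Multiplying one half-plane of the image
transform by the unit-modulus complex transfer CTFP and the conjugate
half-plane by CTFQ instead relocalises *one* sideband exactly onto the
particle (the other is pushed twice as far out and removed by a soft mask),
yielding a clean per-frequency measurement of a single 3D Fourier sample.

Because the half-plane assignment is discontinuous along its boundary axis,
the correction is run in several passes with rotated boundaries and, for
every frequency, the pass whose boundary is angularly farthest supplies the
final sample (the multi-sector procedure).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fourier import (
    FourierImage,
    centered_fft2,
    centered_ifft2,
    freq_grid,
    nyquist_disc,
)
from .geometry import min_defocus
from .optics import OpticalModel, chi, ctf_p, ctf_q, ctf_r


@dataclass(frozen=True)
class SectorPlan:
    """Rotated-boundary passes realising a 2*len(rotations)-sector correction.

    ``rotations`` lists the boundary-axis angles (radians); each pass keeps
    the frequencies within ``keep_margin`` of the axis perpendicular to its
    boundary.  The default (4 passes at 0, 45, 90, 135 deg, margin 22.5 deg)
    realises the 8-sector scheme; the single-pass plans used for worked
    examples are built with :meth:`single`.
    """

    rotations: tuple = field(default=(0.0, np.pi / 4, np.pi / 2, 3 * np.pi / 4))
    keep_margin: float = np.pi / 8

    def __post_init__(self) -> None:
        if len(self.rotations) == 0:
            raise ValueError("need at least one boundary rotation")
        if not 0 < self.keep_margin <= np.pi / 2:
            raise ValueError("keep_margin must be in (0, pi/2]")
        # every azimuth must be interior to some pass's kept region
        probe = np.linspace(0, np.pi, 721)
        covered = np.zeros_like(probe, dtype=bool)
        for beta in self.rotations:
            dist = _line_distance(probe, beta + np.pi / 2)
            covered |= dist <= self.keep_margin + 1e-12
        if not covered.all():
            raise ValueError("sector plan does not cover all azimuths")

    @property
    def n_sectors(self) -> int:
        return 2 * len(self.rotations)

    @classmethod
    def single(cls, boundary_angle: float) -> "SectorPlan":
        """One-pass plan with an arbitrary boundary axis (coarse but simple)."""
        return cls(rotations=(boundary_angle,), keep_margin=np.pi / 2)


@dataclass(frozen=True)
class MaskSpec:
    """Radial soft window: ~1 inside diameter/2, fall-off over edge_width.

    ``profile`` selects the edge shape: 'gaussian' (erf edge, i.e. a disc
    smoothed with a Gaussian; spectral sidelobes decay like a Gaussian) or
    'cosine' (raised cosine; only C1, so its window tails decay as a power
    law and can leak strong low-frequency power into weak high-frequency
    samples).  The gaussian profile is the default for exactly that reason.
    """

    diameter: float  # plateau diameter, Angstrom
    edge_width: float  # fall-off width, Angstrom
    center: tuple | None = None  # pixel coordinates; None = box centre
    profile: str = "gaussian"

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.edge_width < 0:
            raise ValueError("mask diameter must be > 0 and edge width >= 0")
        if self.profile not in ("gaussian", "cosine"):
            raise ValueError("profile must be 'gaussian' or 'cosine'")

    @classmethod
    def for_particle(cls, particle_diameter: float) -> "MaskSpec":
        """Default particle mask: half-transmission at 0.6 D radius.

        Plateau 0.8 D with a 0.4 D Gaussian edge, i.e. a 1.2 D diameter at
        half height -- generous enough not to clip the particle, compact
        enough to exclude fully separated ghost sidebands.
        """
        return cls(diameter=0.8 * particle_diameter, edge_width=0.4 * particle_diameter)

    @classmethod
    def for_conditions(
        cls,
        particle_diameter: float,
        defocus: float,
        wavelength: float,
        max_spatial_freq: float,
    ) -> "MaskSpec":
        """Mask sized to the delocalisation geometry of a dataset.

        When the finest spacings are fully separated (ghost displacement
        2 dF lambda s beyond ~1.2 D), the particle-sized mask removes the
        wrong-sideband ghosts -- the purpose of masking.  Below that
        threshold nothing is separated, clipping would mutilate the
        overlapped content, and the plateau instead grows to hold the
        largest ghost displacement.
        """
        shift = 2.0 * defocus * wavelength * max_spatial_freq
        if shift >= 1.2 * particle_diameter:
            return cls.for_particle(particle_diameter)
        return cls(
            diameter=particle_diameter + 2.0 * shift,
            edge_width=0.4 * particle_diameter,
        )


@dataclass
class SidebandSamples:
    """Per-frequency extraction from one particle image, one side.

    ``amp``/``phs`` encode the complex Fourier sample; ``zstar`` is its
    signed offset (1/A) from the central section, +-lambda*|s|^2/2 with the
    sign depending on side and on which half-plane of the selected pass the
    frequency fell in.  The P and Q extractions of the same image carry
    opposite zstar maps.
    """

    amp: np.ndarray
    phs: np.ndarray
    zstar: np.ndarray
    side: str
    pixel_size: float

    def __post_init__(self) -> None:
        if self.side not in ("P", "Q"):
            raise ValueError("side must be 'P' or 'Q'")
        if np.any(self.amp < 0):
            raise ValueError("amplitudes must be non-negative")

    @property
    def values(self) -> np.ndarray:
        """Complex samples amp * exp(i * phs), centred layout."""
        return self.amp * np.exp(1j * self.phs)


def _line_distance(phi, beta):
    """Angular distance (mod pi) of azimuths phi from the line at angle beta."""
    ang = np.mod(np.asarray(phi) - beta, np.pi)
    return np.minimum(ang, np.pi - ang)


def _halfplane_sign(n: int, boundary_angle: float) -> np.ndarray:
    """+1/-1 per centred frequency: which side of the boundary axis it is on.

    Frequencies exactly on the boundary line follow the axis rule: the ray
    along +boundary direction goes with the positive half, the opposite ray
    with the negative half, so Friedel mates always land on opposite sides.
    """
    k = np.arange(n, dtype=float) - n // 2
    kx = k[:, None]
    ky = k[None, :]
    ux, uy = np.cos(boundary_angle), np.sin(boundary_angle)
    t = -uy * kx + ux * ky  # component along the boundary normal
    a = ux * kx + uy * ky  # component along the boundary axis
    on_line = np.abs(t) <= 1e-9 * np.maximum(np.abs(kx) + np.abs(ky), 1.0)
    sign = np.where(on_line, np.sign(a), np.sign(t))
    return sign


def _sideband_multiplier(
    n: int, pixel_size: float, model: OpticalModel, boundary_angle: float, side: str
) -> np.ndarray:
    """Complex multiplier implementing one CTFP/CTFQ half-plane pass."""
    if side not in ("P", "Q"):
        raise ValueError("side must be 'P' or 'Q'")
    _, _, s_mag, azimuth = freq_grid(n, pixel_size)
    chi_grid = chi(s_mag, azimuth, model)
    p = ctf_p(chi_grid, model)
    q = ctf_q(chi_grid, model)
    sign = _halfplane_sign(n, boundary_angle)
    mult = np.where(sign > 0, p, q) if side == "P" else np.where(sign > 0, q, p)
    disc = nyquist_disc(n)
    mult = np.where(disc, mult, 0.0)
    mult[n // 2, n // 2] = 1.0  # the DC term carries no phase-contrast information
    return mult


def apply_complex_ctf(
    image_ft: FourierImage, model: OpticalModel, boundary_angle: float, side: str
) -> FourierImage:
    """Multiply one half-plane by CTFP and the conjugate half by CTFQ.

    ``side='P'`` puts CTFP on the positive side of the boundary axis,
    ``side='Q'`` swaps the roles.  The zero frequency is untouched and
    frequencies on/beyond the inscribed Nyquist circle are zeroed, so the
    output of a Hermitian input is Hermitian and its inverse transform real.
    """
    if not image_ft.is_hermitian(1e-8):
        raise ValueError(
            "input transform is not Hermitian (did it come from a real image?)"
        )
    mult = _sideband_multiplier(
        image_ft.n, image_ft.pixel_size, model, boundary_angle, side
    )
    return FourierImage(image_ft.values * mult, image_ft.pixel_size)


def apply_real_ctf(
    image_ft: FourierImage, model: OpticalModel, normalized: bool = False
) -> FourierImage:
    """Conventional real CTF correction (multiplication by CTFR).

    With ``normalized`` the standard unit-amplitude form CTFR/2 (i.e. -sin
    chi for zero amplitude contrast) is applied instead.  Band-limited to
    the same Nyquist disc as the complex passes, so CTFP + CTFQ application
    equals this exactly.
    """
    n = image_ft.n
    _, _, s_mag, azimuth = freq_grid(n, image_ft.pixel_size)
    mult = ctf_r(chi(s_mag, azimuth, model), model)
    if normalized:
        mult = mult / 2.0
    mult = np.where(nyquist_disc(n), mult, 0.0)
    # DC passes untouched through each complex pass, so the sum convention
    # carries it with weight 2 (1 after normalisation): CTFP + CTFQ = CTFR
    # holds at every frequency including zero
    mult[n // 2, n // 2] = 1.0 if normalized else 2.0
    return FourierImage(image_ft.values * mult, image_ft.pixel_size)


def soft_mask(
    image: np.ndarray,
    center: tuple | None,
    diameter: float,
    edge_width: float,
    pixel_size: float,
    profile: str = "gaussian",
) -> np.ndarray:
    """Multiply by a radial soft-edged window (~1 inside diameter/2).

    ``center`` is in pixel coordinates (axis-0, axis-1); None means the box
    centre N/2.  The window must fit inside the image.  ``profile``:
    'gaussian' (erf edge centred on diameter/2 + edge/2) or 'cosine'
    (raised cosine over [diameter/2, diameter/2 + edge]).
    """
    from scipy.special import erfc

    img = np.asarray(image, dtype=float)
    n0, n1 = img.shape
    if center is None:
        center = (n0 // 2, n1 // 2)
    r_plateau = diameter / 2.0
    if r_plateau + edge_width > 0.5 * min(n0, n1) * pixel_size + 1e-9:
        raise ValueError("mask (diameter + 2*edge) exceeds the image bounds")
    x = (np.arange(n0) - center[0])[:, None] * pixel_size
    y = (np.arange(n1) - center[1])[None, :] * pixel_size
    r = np.hypot(x, y)
    if edge_width == 0:
        window = (r <= r_plateau).astype(float)
    elif profile == "cosine":
        t = np.clip((r - r_plateau) / edge_width, 0.0, 1.0)
        window = 0.5 * (1.0 + np.cos(np.pi * t))
    elif profile == "gaussian":
        sigma = edge_width / 4.0
        window = 0.5 * erfc((r - r_plateau - edge_width / 2.0) / (np.sqrt(2.0) * sigma))
    else:
        raise ValueError("profile must be 'gaussian' or 'cosine'")
    return img * window


def mask_window(shape, mask: MaskSpec, pixel_size: float) -> np.ndarray:
    """The soft window itself (ones image through soft_mask)."""
    return soft_mask(
        np.ones(shape), mask.center, mask.diameter, mask.edge_width, pixel_size,
        profile=mask.profile,
    )


def _select_pass(n: int, plan: SectorPlan) -> np.ndarray:
    """Per-frequency index of the pass whose boundary is angularly farthest."""
    k = np.arange(n, dtype=float) - n // 2
    phi = np.arctan2(k[None, :], k[:, None])  # azimuth of (kx, ky)
    dists = np.stack([_line_distance(phi, beta) for beta in plan.rotations])
    return np.argmax(dists, axis=0)


def sideband_correct(
    image: np.ndarray,
    model: OpticalModel,
    plan: SectorPlan | None = None,
    mask: MaskSpec | None = None,
    pixel_size: float = 1.0,
    particle_diameter: float | None = None,
):
    """Run the full multi-sector single-sideband extraction on one image.

    For every pass (rotated boundary) and each of the two sides the image
    transform is multiplied half-plane-wise by CTFP/CTFQ, inverse
    transformed, soft-masked around the particle and re-transformed.  Each
    final Fourier sample is taken from the pass whose boundary axis is
    farthest from that frequency's azimuth, and is tagged with its signed
    z* offset +-lambda|s|^2/2.

    Returns a (P, Q) pair of :class:`SidebandSamples`.  ``mask=None`` skips
    masking (useful for exact algebraic identities).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("image must be square and 2D")
    n = img.shape[0]
    plan = plan or SectorPlan()
    if particle_diameter is not None:
        d_nyq = 2.0 * pixel_size
        df_min = min_defocus(particle_diameter, d_nyq, model.wavelength)
        if model.defocus < df_min:
            from .weighting import OverlapInput, overlap_fraction

            a_nyq = overlap_fraction(
                OverlapInput(model.defocus, d_nyq, particle_diameter, model.wavelength)
            )
            warnings.warn(
                f"defocus {model.defocus:.0f} A below the full-separation "
                f"threshold {df_min:.0f} A at Nyquist; sidebands overlap "
                f"(A={a_nyq:.3f}) in the affected shells",
                stacklevel=2,
            )

    # contrast images are processed zero-mean: the DC term carries no
    # structural information (it is never inserted) and a constant offset
    # would otherwise leak the window's own spectrum into every sample
    ft = FourierImage.from_real_image(img - img.mean(), pixel_size)
    window = mask_window(img.shape, mask, pixel_size) if mask is not None else None

    per_pass: dict[str, list[np.ndarray]] = {"P": [], "Q": []}
    for beta in plan.rotations:
        for side in ("P", "Q"):
            corrected = apply_complex_ctf(ft, model, beta, side)
            real_img = corrected.to_real_image()
            if window is not None:
                real_img = real_img * window
            per_pass[side].append(centered_fft2(real_img))

    sel = _select_pass(n, plan)
    signs = np.stack([_halfplane_sign(n, beta) for beta in plan.rotations])
    sel_sign = np.take_along_axis(signs, sel[None], axis=0)[0]
    disc = nyquist_disc(n)
    _, _, s_mag, _ = freq_grid(n, pixel_size)
    dz = 0.5 * model.wavelength * s_mag**2

    out = []
    for side in ("P", "Q"):
        stack = np.stack(per_pass[side])
        g = np.take_along_axis(stack, sel[None], axis=0)[0]
        g = np.where(disc, g, 0.0)
        # CTFP applied on the positive half extracts the -dz* sample there
        side_eta = -1.0 if side == "P" else 1.0
        zstar = np.where(disc, side_eta * sel_sign * dz, 0.0)
        out.append(
            SidebandSamples(
                amp=np.abs(g),
                phs=np.angle(g),
                zstar=zstar,
                side=side,
                pixel_size=pixel_size,
            )
        )
    return tuple(out)


def fringe_centroid(
    image: np.ndarray,
    freq_xy: tuple,
    pixel_size: float,
    band_sigma: float | None = None,
):
    """Centroid (A, relative to box centre) of the band-passed fringe energy.

    The image transform is windowed by a Gaussian centred on +freq_xy (one
    sideband of the band only, giving the analytic signal) and the centroid
    of the squared envelope is returned.  ``band_sigma`` is the spectral
    window width in 1/A; default three frequency steps.
    """
    img = np.asarray(image, dtype=float)
    n = img.shape[0]
    if band_sigma is None:
        band_sigma = 3.0 / (n * pixel_size)
    sx, sy, _, _ = freq_grid(n, pixel_size)
    band = np.exp(
        -((sx - freq_xy[0]) ** 2 + (sy - freq_xy[1]) ** 2) / (2.0 * band_sigma**2)
    )
    analytic = centered_ifft2(centered_fft2(img) * band)
    energy = np.abs(analytic) ** 2
    total = energy.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError("no power at the requested frequency; centroid undefined")
    coords = (np.arange(n) - n // 2) * pixel_size
    cx = (energy.sum(axis=1) * coords).sum() / total
    cy = (energy.sum(axis=0) * coords).sum() / total
    return float(cx), float(cy)


def relocalization_distance(
    image_before: np.ndarray,
    image_after: np.ndarray,
    freq_xy: tuple,
    pixel_size: float,
    band_sigma: float | None = None,
) -> float:
    """Distance (A) between the fringe-energy centroids of two images."""
    bx, by = fringe_centroid(image_before, freq_xy, pixel_size, band_sigma)
    ax, ay = fringe_centroid(image_after, freq_xy, pixel_size, band_sigma)
    return float(np.hypot(ax - bx, ay - by))
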