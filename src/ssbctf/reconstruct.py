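"""Curved-sphere 3D Fourier insertion, FSC, and the three-map hand report.

Each corrected sideband sample is placed at R (sx, sy, z*) in the 3D
transform (trilinear gridding) and the map is formed as a Wiener-stabilised
ratio

    map = sum_n sum_{p,q} sample / (sum_n sum_{p,q} W^2/(1+A) + w).

The numerator is unweighted: where the two sideband estimates of a
coefficient land on the same voxel they interfere to build the correct
weight themselves.  The denominator counts W^2 once per *independent*
estimate: a sample in the fully separated band (A = 0) is one estimate,
while at full overlap the p and q insertions duplicate the same coefficient,
so each contributes W^2/2.  The 1/(1+A) factor interpolates between the two
regimes and makes the flat, full-overlap limit agree exactly with the
conventional CTFR reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fourier import (
    centered_fft2,
    centered_fftn,
    centered_ifftn,
    freq_grid,
    hermitianize,
    nyquist_disc,
)
from .optics import OpticalModel, chi, ctf_p, ctf_r
from .sideband import MaskSpec, SectorPlan, SidebandSamples, sideband_correct, soft_mask
from .weighting import insertion_weight, overlap_area_fraction


@dataclass
class ParticleRecord:
    """Metadata for one boxed particle."""

    defocus: float  # Angstrom, positive = underfocus
    orientation: np.ndarray  # 3x3 rotation matrix
    diameter: float  # Angstrom
    pixel_size: float  # Angstrom / pixel
    stack_index: int = 0

    def __post_init__(self) -> None:
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 rotation matrix")
        if self.diameter <= 0 or self.pixel_size <= 0:
            raise ValueError("diameter and pixel size must be positive")


@dataclass
class MapAccumulator:
    """Numerator/denominator sums of the weighted 3D Fourier insertion.

    Samples are gridded onto a Fourier grid oversampled by ``oversample``
    (finer frequency spacing reduces trilinear gridding artifacts); the
    finalised map is cropped back to n^3 and divided by the trilinear
    kernel's real-space envelope (sinc^2 gridding correction).
    """

    n: int
    pixel_size: float
    oversample: int = 2
    numerator: np.ndarray = field(init=False)
    denominator: np.ndarray = field(init=False)
    n_skipped: int = field(default=0, init=False)

    def __post_init__(self) -> None:
        if self.n % 2 != 0:
            raise ValueError("grid size must be even")
        if self.oversample < 1:
            raise ValueError("oversample must be >= 1")
        m = self.oversample * self.n
        self.numerator = np.zeros((m,) * 3, dtype=complex)
        self.denominator = np.zeros((m,) * 3)

    @property
    def grid_size(self) -> int:
        return self.oversample * self.n

    def voxel_coords(self, recip: np.ndarray) -> np.ndarray:
        """Reciprocal coordinates (1/A, shape (3, M)) -> fractional voxels."""
        m = self.grid_size
        return recip * (m * self.pixel_size) + m // 2

    def scatter(self, coords: np.ndarray, values: np.ndarray, weights: np.ndarray) -> None:
        """Trilinear spread of samples at fractional voxel coords (3, M)."""
        n = self.grid_size
        base = np.floor(coords).astype(int)
        frac = coords - base
        ok = np.all((base >= 0) & (base + 1 <= n - 1), axis=0)
        self.n_skipped += int((~ok).sum())
        base, frac = base[:, ok], frac[:, ok]
        vals, wts = values[ok], weights[ok]
        num_flat = self.numerator.ravel()
        den_flat = self.denominator.ravel()
        for dx in (0, 1):
            wx = frac[0] if dx else 1.0 - frac[0]
            for dy in (0, 1):
                wy = frac[1] if dy else 1.0 - frac[1]
                for dz in (0, 1):
                    wz = frac[2] if dz else 1.0 - frac[2]
                    w = wx * wy * wz
                    idx = ((base[0] + dx) * n + base[1] + dy) * n + base[2] + dz
                    np.add.at(num_flat, idx, vals * w)
                    np.add.at(den_flat, idx, wts * w)

    def finalize(self, wiener: float | None = None) -> np.ndarray:
        """Wiener-stabilised ratio, Hermitian-projected, back to real space.

        Returns the n^3 map (oversampling cropped away, trilinear gridding
        envelope divided out).
        """
        if wiener is None:
            nz = self.denominator[self.denominator > 0]
            wiener = 0.1 * nz.mean() if nz.size else 1.0
        if wiener <= 0:
            raise ValueError("Wiener factor must be positive")
        f = self.numerator / (self.denominator + wiener)
        f = hermitianize(f)
        big = centered_ifftn(f).real
        m, n = self.grid_size, self.n
        lo = m // 2 - n // 2
        vol = big[lo : lo + n, lo : lo + n, lo : lo + n]
        # real-space envelope of the trilinear spreading kernel
        x = (np.arange(n) - n // 2) / m
        env1 = np.sinc(x) ** 2
        env = env1[:, None, None] * env1[None, :, None] * env1[None, None, :]
        return vol / env


_RETENTION_CACHE: dict = {}


def ghost_retention_curve(mask: MaskSpec | None, diameter: float, pixel_size: float):
    """Fraction of a displaced ghost disc the soft mask retains, vs distance.

    Returns (distances, fractions): the window-weighted mean over a disc of
    the particle diameter whose centre sits ``t`` away from the mask centre,
    for t from 0 to where it reaches 0.  With no mask everything is
    retained (g = 1).  For a hard mask of exactly the particle diameter this
    reduces to the two-disc overlap-area fraction of Eq.-7 type geometry.
    """
    if mask is None:
        t = np.array([0.0, 1.0])
        return t, np.ones(2)
    key = (mask.diameter, mask.edge_width, mask.profile, round(diameter, 6))
    if key in _RETENTION_CACHE:
        return _RETENTION_CACHE[key]
    from .sideband import mask_window

    step = max(diameter / 64.0, pixel_size / 2.0)
    half = mask.diameter / 2.0 + mask.edge_width + diameter
    ngrid = int(np.ceil(2 * half / step / 2)) * 2 + 32
    window = mask_window((ngrid, ngrid), MaskSpec(
        diameter=mask.diameter, edge_width=mask.edge_width, profile=mask.profile
    ), step)
    co = (np.arange(ngrid) - ngrid // 2) * step
    x = co[:, None]
    y = co[None, :]
    t_max = mask.diameter / 2.0 + mask.edge_width + diameter / 2.0
    distances = np.linspace(0.0, t_max, 64)
    fractions = np.empty_like(distances)
    for i, t in enumerate(distances):
        disc = (x - t) ** 2 + y**2 <= (diameter / 2.0) ** 2
        fractions[i] = window[disc].mean()
    _RETENTION_CACHE[key] = (distances, fractions)
    return distances, fractions


def _per_sample_weights(
    n: int,
    model: OpticalModel,
    particle: ParticleRecord,
    mode: str,
    mask: MaskSpec | None,
) -> np.ndarray:
    """Per-sample denominator weight grid for one particle.

    mode='interference': 1 + g Re(CTFP^2) -- the exact magnitude
    bookkeeping of the p,q superposition in the numerator: a masked sample
    is the true coefficient plus the g-attenuated wrong-sideband ghost, so
    the pair sums to (2 + 2 g Re(CTFP^2)) x truth.  The retention g is the
    fraction of the ghost disc (displaced by 2 dF lambda / d) the actual
    soft mask keeps; for a hard particle-sized mask g equals the overlap
    fraction A.  mode='eq6': W^2/(1+A) with the |sin chi|-interpolated
    weight W of the overlap model; the 1+A factor counts the duplicate
    estimates the numerator superposes.  Both modes coincide in the fully
    separated band (weight 1) and at full overlap (pairwise CTFR^2).
    """
    _, _, s_mag, azimuth = freq_grid(n, particle.pixel_size)
    chi_grid = chi(s_mag, azimuth, model)
    if mode == "interference":
        dist, frac = ghost_retention_curve(mask, particle.diameter, particle.pixel_size)
        ghost_shift = 2.0 * particle.defocus * model.wavelength * s_mag
        g = np.interp(ghost_shift, dist, frac, right=0.0)
        return 1.0 + g * np.real(ctf_p(chi_grid, model) ** 2)
    if mode == "eq6":
        u = 2.0 * particle.defocus * model.wavelength * s_mag / particle.diameter
        a = overlap_area_fraction(u)
        w = insertion_weight(chi_grid, a)
        return w * w / (1.0 + a)
    raise ValueError("denominator_mode must be 'interference' or 'eq6'")


def insert_particle(
    acc: MapAccumulator,
    samples: tuple[SidebandSamples, SidebandSamples],
    orientation: np.ndarray,
    particle: ParticleRecord,
    model: OpticalModel,
    curvature_direction: int = 1,
    denominator_mode: str = "interference",
    mask: MaskSpec | None = None,
) -> MapAccumulator:
    """Insert one particle's P/Q sideband samples into the accumulator.

    ``curvature_direction`` +1 inserts each sample at its extracted z*
    offset, -1 at the negated offset, 0 on the central section (flat).
    Samples beyond the grid Nyquist are skipped and counted.
    """
    if curvature_direction not in (-1, 0, 1):
        raise ValueError("curvature_direction must be +1, 0 or -1")
    r = np.asarray(orientation, dtype=float)
    n = samples[0].amp.shape[0]  # image grid; may differ from the map grid
    den_grid = _per_sample_weights(n, model, particle, denominator_mode, mask)
    sx, sy, s_mag, _ = freq_grid(n, particle.pixel_size)
    keep = nyquist_disc(n) & (s_mag > 0)

    for smp in samples:
        if smp.amp.shape != (n, n):
            raise ValueError("P and Q sample grids disagree")
        vec = np.stack(
            [
                sx[keep],
                sy[keep],
                curvature_direction * smp.zstar[keep],
            ]
        )
        coords = acc.voxel_coords(r @ vec)
        acc.scatter(coords, smp.values[keep], den_grid[keep])
    return acc


def conventional_reconstruct(
    images,
    records,
    model: OpticalModel,
    n: int | None = None,
    wiener: float | None = None,
) -> np.ndarray:
    """Flat-sphere baseline: CTFR-weighted central-section insertion (Wiener).

    Numerator accumulates CTFR * image transform on the central section,
    denominator CTFR^2, per the conventional weighted summation.
    """
    records = list(records)
    images = list(images)
    if len(images) != len(records):
        raise ValueError(f"{len(images)} images but {len(records)} metadata records")
    if n is None:
        n = images[0].shape[0]
    acc = MapAccumulator(n, records[0].pixel_size)
    for img, rec in zip(images, records):
        px = rec.pixel_size
        m = OpticalModel(
            voltage_kev=model.voltage_kev,
            defocus=rec.defocus,
            cs=model.cs,
            amp_contrast=model.amp_contrast,
            extra_phase=model.extra_phase,
            wavelength=model.wavelength,
            paper_lambda=model.paper_lambda,
        )
        img = np.asarray(img, dtype=float)
        n_img = img.shape[0]
        ft = centered_fft2(img)
        sx, sy, s_mag, azimuth = freq_grid(n_img, px)
        ctf = ctf_r(chi(s_mag, azimuth, m), m)
        keep = nyquist_disc(n_img) & (s_mag > 0)
        vec = np.stack([sx[keep], sy[keep], np.zeros(keep.sum())])
        coords = acc.voxel_coords(np.asarray(rec.orientation) @ vec)
        acc.scatter(coords, (ctf * ft)[keep], (ctf * ctf)[keep])
    return acc.finalize(wiener)


def fsc(map_a: np.ndarray, map_b: np.ndarray, shell_width: float = 1.0):
    """Fourier shell correlation between two maps on the same grid.

    ``shell_width`` is in voxel-frequency units (1 = one voxel step).
    Returns (radii_voxels, fsc_values); divide radii by N*pixel for 1/A.
    """
    a = np.asarray(map_a, dtype=float)
    b = np.asarray(map_b, dtype=float)
    if a.shape != b.shape or a.ndim != 3:
        raise ValueError("maps must be 3D arrays on the same grid")
    n = a.shape[0]
    fa = centered_fftn(a)
    fb = centered_fftn(b)
    k = np.arange(n) - n // 2
    r = np.sqrt(
        k[:, None, None] ** 2 + k[None, :, None] ** 2 + k[None, None, :] ** 2
    )
    shells = np.floor(r / shell_width + 0.5).astype(int)
    n_shells = n // 2 + 1
    flat = shells.ravel()
    keep = flat < n_shells
    cross = np.bincount(
        flat[keep], weights=(fa * np.conj(fb)).real.ravel()[keep], minlength=n_shells
    )
    pa = np.bincount(flat[keep], weights=(np.abs(fa) ** 2).ravel()[keep], minlength=n_shells)
    pb = np.bincount(flat[keep], weights=(np.abs(fb) ** 2).ravel()[keep], minlength=n_shells)
    denom = np.sqrt(pa * pb)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = np.where(denom > 0, cross / denom, 0.0)
    radii = np.arange(n_shells) * shell_width
    return radii, curve


def map_correlation(map_a: np.ndarray, map_b: np.ndarray) -> float:
    """Real-space Pearson correlation between two maps."""
    a = np.asarray(map_a, dtype=float).ravel()
    b = np.asarray(map_b, dtype=float).ravel()
    return float(np.corrcoef(a, b)[0, 1])


def bandlimited_masked_truth(volume: np.ndarray, mask: MaskSpec, pixel_size: float) -> np.ndarray:
    """Reference volume comparable to a reconstruction: 3D soft mask applied
    in real space, then band-limited to the inscribed Nyquist sphere."""
    vol = np.asarray(volume, dtype=float)
    n = vol.shape[0]
    coords = (np.arange(n) - n // 2) * pixel_size
    r = np.sqrt(
        coords[:, None, None] ** 2
        + coords[None, :, None] ** 2
        + coords[None, None, :] ** 2
    )
    r0 = mask.diameter / 2.0
    if mask.edge_width == 0:
        window = (r <= r0).astype(float)
    elif mask.profile == "cosine":
        t = np.clip((r - r0) / mask.edge_width, 0.0, 1.0)
        window = 0.5 * (1.0 + np.cos(np.pi * t))
    else:
        from scipy.special import erfc

        sigma = mask.edge_width / 4.0
        window = 0.5 * erfc((r - r0 - mask.edge_width / 2.0) / (np.sqrt(2.0) * sigma))
    masked = vol * window
    f = centered_fftn(masked)
    k = np.arange(n) - n // 2
    kr2 = k[:, None, None] ** 2 + k[None, :, None] ** 2 + k[None, None, :] ** 2
    f[kr2 >= (n // 2) ** 2] = 0.0
    return centered_ifftn(f).real


def reconstruct_from_particles(
    images,
    records,
    model: OpticalModel,
    curvature_direction: int = 1,
    plan: SectorPlan | None = None,
    mask: MaskSpec | None = None,
    wiener: float | None = None,
    map_size: int | None = None,
    denominator_mode: str = "interference",
    return_accumulator: bool = False,
):
    """simulate/extracted images -> sideband correction -> 3D map.

    ``map_size`` (default: the image size) sets the reconstruction grid;
    images may be boxed larger than the map to hold delocalised fringes.
    """
    images = list(images)
    records = list(records)
    n = map_size or images[0].shape[0]
    acc = MapAccumulator(n, records[0].pixel_size)
    for img, rec in zip(images, records):
        m = OpticalModel(
            voltage_kev=model.voltage_kev,
            defocus=rec.defocus,
            cs=model.cs,
            amp_contrast=model.amp_contrast,
            extra_phase=model.extra_phase,
            wavelength=model.wavelength,
            paper_lambda=model.paper_lambda,
        )
        part_mask = mask or MaskSpec.for_conditions(
            rec.diameter, rec.defocus, m.wavelength, 0.5 / rec.pixel_size
        )
        samples = sideband_correct(
            img, m, plan=plan, mask=part_mask, pixel_size=rec.pixel_size,
        )
        insert_particle(
            acc, samples, rec.orientation, rec, m, curvature_direction,
            denominator_mode=denominator_mode, mask=part_mask,
        )
    if return_accumulator:
        return acc
    return acc.finalize(wiener)


def mirrored_records(records):
    """Relabel particle metadata as views of the mirrored specimen.

    A specimen and its mirror produce identical flat projections when the
    orientations are conjugated by the z-flip (R -> M R M, M = diag(1,1,-1));
    only the Ewald-curvature direction distinguishes the two hand
    hypotheses.  Reconstructing with these orientations and the opposite
    curvature direction yields exactly the mirror of the original map.
    """
    m = np.diag([1.0, 1.0, -1.0])
    out = []
    for rec in records:
        out.append(
            ParticleRecord(
                defocus=rec.defocus,
                orientation=m @ rec.orientation @ m,
                diameter=rec.diameter,
                pixel_size=rec.pixel_size,
                stack_index=rec.stack_index,
            )
        )
    return out


def separated_band_shells(
    n: int, pixel_size: float, defocus: float, diameter: float, wavelength: float
) -> np.ndarray:
    """Boolean per-shell mask: shells with A = 0 (fully separated sidebands),
    below 95% of Nyquist (the top shells are interpolation-limited)."""
    radii = np.arange(n // 2 + 1)
    s = radii / (n * pixel_size)
    u = 2.0 * defocus * wavelength * s / diameter
    return (u >= 1.0) & (radii <= 0.95 * (n // 2)) & (radii > 0)


def hand_and_curvature_report(
    images,
    records,
    model: OpticalModel,
    ground_truth,
    plan: SectorPlan | None = None,
    mask: MaskSpec | None = None,
    wiener: float | None = None,
) -> dict:
    """Reconstruct with z* applied correctly, flat, and inverted; score each.

    The score per direction is the mean FSC against the (masked,
    band-limited) ground truth over the shells where the sidebands are
    fully separated -- the band where the curvature treatment can matter.
    The direction with the best score is declared the winner; on data whose
    curvature convention matches the simulator's this is +1, and comparing
    against the mirrored truth instead flips the winner to -1.
    """
    images = list(images)
    records = list(records)
    px = records[0].pixel_size
    part_mask = mask or MaskSpec.for_particle(records[0].diameter)

    truth_vol = ground_truth.values if hasattr(ground_truth, "values") else ground_truth
    truth = bandlimited_masked_truth(np.asarray(truth_vol, dtype=float), part_mask, px)
    n = truth.shape[0]  # reconstruct on the ground-truth grid

    # correct once, insert three times
    corrected = []
    for img, rec in zip(images, records):
        m = OpticalModel(
            voltage_kev=model.voltage_kev,
            defocus=rec.defocus,
            cs=model.cs,
            amp_contrast=model.amp_contrast,
            extra_phase=model.extra_phase,
            wavelength=model.wavelength,
            paper_lambda=model.paper_lambda,
        )
        rec_mask = mask or MaskSpec.for_conditions(
            rec.diameter, rec.defocus, m.wavelength, 0.5 / rec.pixel_size
        )
        corrected.append(
            (
                sideband_correct(
                    img, m, plan=plan, mask=rec_mask, pixel_size=rec.pixel_size
                ),
                rec,
                m,
                rec_mask,
            )
        )

    shell_sel = separated_band_shells(
        n, px, records[0].defocus, records[0].diameter, model.wavelength
    )
    report: dict = {"directions": {}, "shell_selection": shell_sel}
    for direction in (1, 0, -1):
        acc = MapAccumulator(n, px)
        for samples, rec, m, rec_mask in corrected:
            insert_particle(
                acc, samples, rec.orientation, rec, m, direction, mask=rec_mask
            )
        vol = acc.finalize(wiener)
        radii, curve = fsc(vol, truth)
        score = float(curve[shell_sel].mean())
        report["directions"][direction] = {
            "map": vol,
            "fsc_radii": radii,
            "fsc": curve,
            "score": score,
        }
    scores = {d: v["score"] for d, v in report["directions"].items()}
    report["scores"] = scores
    report["best_direction"] = max(scores, key=scores.get)
    return report
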