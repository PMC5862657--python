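# Methods

## Image-formation model and conventions

All optics use the aberration phase

    chi(s) = -(2*pi/lambda) * (dF*theta^2/2 - Cs*theta^4/4),  theta = lambda*s,

with positive defocus `dF` meaning underfocus.  In this sign convention chi
is negative at low resolution for an underfocused image and the conventional
transfer function `CTFR = -2 sin(chi)` carries positive low-resolution
contrast.  Displays elsewhere often print underfocus as a negative number;
that is a labelling convention only.

Amplitude contrast W is folded into the phase of the single-sideband
factors, `CTFP = exp(+i*(chi + pi/2 - arcsin W))`, `CTFQ = conj(CTFP)`, so
that the sum identity

    CTFP + CTFQ = 2*(W*cos chi - sqrt(1-W^2)*sin chi)

holds to machine precision and the combined term reinforces the phase
contrast at underfocus (the physically correct pairing in this chi
convention).  The total phase shift on scattering is 90 deg + arcsin(W) —
about 94 deg at W = 0.07 — a number usually quoted in the opposite,
underfocus-positive chi convention; `OpticalModel.scattering_phase_deg`
reports it that way.  Wavelengths are computed relativistically from the
voltage; `paper_lambda=True` substitutes the rounded textbook values (0.02 A
at 300 keV, 0.037 A at 100 keV) so printed worked examples reproduce
exactly.  `voltage_for_wavelength` inverts the relation, which keeps models
self-consistent at scaled wavelengths.

The weak-phase forward model samples the phantom's 3D transform twice per
image frequency,

    I_hat(s) = CTFP(s)*F(R(s_x, s_y, +dz*)) + CTFQ(s)*F(R(s_x, s_y, -dz*)),

with `dz* = lambda*|s|^2/2`.  Pairing the conjugate unit-modulus factors
with mirrored z* offsets makes I_hat Hermitian, hence the image real.
Forcing dz* to zero collapses both samples onto the central section and the
model reduces *exactly* (pointwise, to rounding) to `CTFR x projection`,
which the tests assert.

### Band limit and DC bookkeeping

Every transfer operation acts inside the open Nyquist disc
`|s| < 1/(2*pixel)` and zeroes the rest.  For even grids the rows at the
Nyquist index have no Friedel partner inside the array, and a unit-modulus
complex multiplier cannot preserve Hermitian symmetry there; excluding the
inscribed circle's boundary makes the algebraic identities (CTFP+CTFQ=CTFR
application, P-then-Q = identity, reality of corrected images) exact on
band-limited images rather than approximate.

The zero frequency carries no phase-contrast information.  Each complex pass
carries it through untouched; the summed (conventional) application
therefore carries it with weight 2, and the forward model uses the same pair
convention.  `sideband_correct` subtracts the image mean before processing:
the DC term is never inserted into the 3D transform, and a constant offset
would otherwise leak the mask window's own spectrum into every extracted
sample.

## The multi-sector correction

One pass multiplies the half-plane on the positive side of a boundary axis
by CTFP and the conjugate half-plane by CTFQ (or the reverse), which keeps
the corrected image real.  Frequencies exactly on the boundary follow the
axis rule: the ray along the +boundary direction goes with the positive
half, its opposite with the negative half, so Friedel mates always receive
conjugate factors.  Near the boundary the assignment is discontinuous, so
the default plan runs four passes with the boundary at 0, 45, 90 and
135 deg (an 8-sector scheme) and, for every frequency, keeps the pass whose
boundary is angularly farthest — each kept sample sits at least 67.5 deg
from the discontinuity.  Single-sector plans with an arbitrary rotation are
available for demonstration figures.

A pass that applies CTFP on the positive half extracts the -dz* sideband
sample there (multiplying the image term `CTFP*F(+dz*)` by CTFP doubles its
delocalisation; multiplying `CTFQ*F(-dz*)` by CTFP relocalises it onto the
particle, where the mask keeps it).  The samples therefore carry a signed
`zstar` map: `-sign_half * lambda|s|^2/2` for the P-side extraction and the
negative of that for Q.  The two extractions together cover both sideband
branches over the full plane exactly once, which is what the 3D insertion
consumes.

## Masking

The soft mask is a radially symmetric window, ~1 inside `diameter/2`,
falling over `edge_width`.  The default profile is a Gaussian-smoothed disc
(erf edge) rather than a raised cosine: the raised cosine is only C^1, its
spectral tails decay as a power law, and on small grids those tails leak the
strong low-frequency content of the retained overlap-band ghost into the
weak separated-band samples at levels that can exceed the true coefficients.
The erf edge has Gaussian tails and eliminates that leakage; the cosine
profile remains available.

Two sizing rules are provided.  `MaskSpec.for_particle(D)` puts the
half-transmission radius at 0.6 D (plateau 0.8 D, edge 0.4 D — a 1.2 D
diameter at half height): generous enough not to clip the particle, compact
enough to exclude fully separated ghosts.  `MaskSpec.for_conditions` checks
whether the finest spacings of a dataset are actually separated (ghost
displacement `2*dF*lambda*s_max` beyond ~1.2 D).  If they are, masking does
its job and the particle mask is used; if nothing is separated (low-defocus,
flat-sphere-like data), clipping would mutilate overlapped content for no
benefit, and the plateau grows to hold the largest ghost displacement.  The
reconstruction pipeline applies this rule per particle when no explicit mask
is given.

## 3D insertion and weighting

Each corrected sample is placed at `R*(s_x, s_y, direction*zstar)` by
trilinear gridding onto a 2x-oversampled Fourier grid; the finalised map is
the Hermitian-projected Wiener ratio, inverse transformed, cropped to the
nominal grid and divided by the trilinear kernel's real-space envelope
(sinc^2 gridding correction).  The Wiener constant defaults to 0.1 x the
mean nonzero denominator; noise-free checks pass a smaller explicit value.

The numerator is unweighted: where the two sideband estimates of a
coefficient land on the same voxel they interfere and build the correct
weight themselves.  The denominator counts, per sample,

    1 + g * Re(CTFP^2),

where `g` is the fraction of the displaced ghost disc that the actual soft
mask retains, computed numerically once per mask/diameter combination
(`ghost_retention_curve`) and evaluated at the ghost displacement
`2*dF*lambda*s`.  For a hard particle-sized mask `g` reduces to the
two-disc overlap-area fraction

    A(u) = (2/pi) * (arccos u - u*sqrt(1-u^2)),   u = 2*dF*lambda/(d*D),

and the bookkeeping reduces to the overlap-model weight
`W = 1 + A*(2|sin chi| - 1)` in both limits: weight 1 per sample where the
sidebands are separated (A = 0), and `CTFR^2` per p,q pair at full overlap —
where the flat-sphere reconstruction coincides with the conventional
CTFR-weighted summation to machine precision (asserted on a small phantom).
At intermediate overlap the interference form is the exact magnitude
bookkeeping of the superposition, including amplitude contrast, while the
|sin chi| form is a linear interpolation; the latter is available as
`denominator_mode="eq6"`.  A sample's overlap fraction, not its voxel
multiplicity, is what controls this: the inner p,q sum contributes one term
where only one sideband lands and two interfering terms where both do.

## Synthetic data

`make_chiral_phantom` builds a right-handed 1.5-turn helix of Gaussian
blobs, each with a sharp core (sigma ~1 px) riding a broader envelope
component.  The cores keep genuine spectral power near Nyquist — the band
where the sidebands separate and curvature matters — playing the role a
strong-lattice test specimen plays experimentally; a smooth-blob phantom has
essentially no signal there and separated-band tests would measure only
numerical leakage.  Density is nonnegative, support is confined inside the
stated diameter, and the mirror correlation is computed at build time
(typically 0.3-0.6, well below the 0.9 bound the hand tests require).

The default study conditions are scaled so Ewald curvature is resolvable on
a desk-size grid: a 64^3 phantom, D = 24 A at 1 A/px, lambda = 0.3 A
(voltage ~2.4 keV via the relativistic relation — the same physics trend
that makes curvature matter for smaller particles at lower energy), images
boxed at 128 px so the box rule `D + 2*dF*lambda/d` holds with room for the
doubled ghost displacement.  At these values `2*dz*` spans ~5 voxels at
Nyquist and D exceeds the significance threshold `d^2/lambda = 13.3 A`.
Amplitude contrast is 0.14, following the trend of W rising as the energy
drops (0.04 at 300 keV, 0.07 at 100 keV).  Curved datasets draw per-particle
defocus uniformly from 120-180 A, comfortably above the separation threshold
`D*d/(2*lambda) = 80 A`, so spacings beyond s ~ 0.27 1/A are fully
separated; the defocus spread also fills each particle's CTF zeros, as it
does in real collections.  Flat-sphere datasets for the degenerate fidelity
check use 30-70 A, the overlap regime in which a flat-sphere dataset would
sensibly be recorded.

What the simulator does *not* model: shot noise envelopes, detector
MTF/DQE, dose and motion, beam tilt, partial coherence, or multiple
scattering.  `add_noise` offers plain seeded white Gaussian noise only.
Passing tests therefore demonstrate the correctness of the correction,
weighting and insertion algebra under ideal weak-phase imaging, not
robustness to the full noise budget of real micrographs.

Orientation convention: rotation matrices act on reciprocal-space sampling
coordinates; tables store ZYZ intrinsic Euler angles in radians.
Off-section values are sampled from the phantom's 2x zero-padded transform
by trilinear interpolation.

## Hand and curvature validation

`hand_and_curvature_report` reconstructs three maps with z* applied
correctly (+1), flat (0) and inverted (-1), and scores each by its mean FSC
against the (masked, band-limited) ground truth over the shells with A = 0
below 95 % of Nyquist — the band where the treatment can matter.  On curved
synthetic data the ordering correct > flat > inverted holds with wide
margins (typically ~0.89 / 0.73 / 0.60 at 40 particles).

The absolute-hand statement is a hypothesis test.  A specimen and its
mirror produce identical flat projections once the orientations are
conjugated by the z-flip (R -> M R M); only the curvature direction
distinguishes the two hands.  `mirrored_records` produces the mirrored-hand
relabelling, and reconstructing it with the opposite curvature direction
yields exactly the mirror of the original map, so scoring both hypotheses
against a reference model decides the hand — and re-running the report
against the mirrored truth with the mirrored records swaps the +1/-1 scores
to four decimals.  Mirroring the truth *alone* does not flip the winner in
general: the inverted-direction map is a superposition of
orientation-dependent mirrors, not a global mirror.  Against a real
instrument one known-hand specimen would still be needed once, to anchor
the sign convention of z* to the physical curvature toward the source.

## Numerical choices

- Tie-break on a sector boundary: the +axis ray goes with the CTFP-side of
  that pass, exactly; implemented with an exact-zero test on the integer
  frequency lattice.
- The overlap fraction's u = 1 point is removable and implemented
  continuously (both branches give 0).
- Trilinear interpolation everywhere (forward sampling and gridding); no
  Kaiser-Bessel kernel.  This is the main resolution-limiting numerical
  approximation and an obvious extension point.
- FSC shells are one voxel-frequency step wide.
- `required_box_size = D + 2*dF*lambda/d` is the minimum; simulations box
  larger because the *wrong*-sideband ghost lands at twice the raw
  delocalisation and must not wrap through the periodic boundary into the
  mask.

## Known limitations

- The scalar retention `g` models only the magnitude of the masked ghost;
  the retained ghost is really a convolution with phase structure.  In the
  overlap-to-separation transition band this leaves percent-level residual
  errors; the flat-sphere end-to-end fidelity is >0.99 under the stated
  conditions but ~0.98 when a transition band carries much of the spectrum.
- Small grids exaggerate window-leakage effects; all tolerances here are
  statements about the stated scaled conditions.
- CTF parameter estimation, per-particle defocus refinement, orientation
  refinement, and map sharpening are out of scope; orientations and defoci
  are taken as given metadata.
- Beam tilt, axial coma and envelope (coherence/detector) factors are not
  modelled; a constant extra phase (phase-plate-like) is the only additional
  aberration term.
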