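import numpy as np
import pytest
from hypothesis import settings

import ssbctf as ssb

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

# Scaled study conditions used by the synthetic-data tests: a 64^3 phantom of
# 24 A diameter at 1 A/px imaged at lambda = 0.3 A in 128 px boxes.  At this
# wavelength the sideband z* offset reaches ~2.4 voxels at Nyquist, so Ewald
# curvature is resolvable on the grid; D exceeds d^2/lambda = 13.3 A, the
# significance threshold.  Amplitude contrast 0.14 follows the trend of W
# rising as the energy drops.
LAMBDA = 0.30
DIAMETER = 24.0
PHANTOM_SIZE = 64
IMAGE_SIZE = 128
AMP_CONTRAST = 0.14
CURVED_DEFOCUS = (120.0, 180.0)  # separation threshold Dd/2lambda = 80 A
FLAT_DEFOCUS = (30.0, 70.0)


def make_model(defocus, amp_contrast=AMP_CONTRAST, wavelength=LAMBDA, cs=0.0):
    return ssb.OpticalModel(
        voltage_kev=ssb.voltage_for_wavelength(wavelength),
        defocus=defocus,
        cs=cs,
        amp_contrast=amp_contrast,
        wavelength=wavelength,
    )


def make_dataset(seed, n_particles, curvature, defocus_range):
    """Phantom + particle images + metadata under the study conditions."""
    from scipy.spatial.transform import Rotation

    phantom = ssb.make_chiral_phantom(PHANTOM_SIZE, 1.0, DIAMETER, seed=seed)
    rots = Rotation.random(n_particles, random_state=np.random.RandomState(100 + seed))
    rng = np.random.default_rng(200 + seed)
    defoci = rng.uniform(*defocus_range, size=n_particles)
    models = [make_model(df) for df in defoci]
    records = [
        ssb.ParticleRecord(
            defocus=df,
            orientation=rot.as_matrix(),
            diameter=DIAMETER,
            pixel_size=1.0,
            stack_index=i,
        )
        for i, (rot, df) in enumerate(zip(rots, defoci))
    ]
    images = [
        ssb.forward_image(phantom, rec.orientation, m, curvature=curvature,
                          image_size=IMAGE_SIZE)
        for rec, m in zip(records, models)
    ]
    return phantom, images, records, models


@pytest.fixture(scope="session")
def fig2_setup():
    """The classic single-fringe demonstration: 80 A particle, -1.1 um
    defocus, one 3.8 A Fourier component, 300 keV (rounded lambda)."""
    model = ssb.OpticalModel(
        voltage_kev=300.0, defocus=11000.0, wavelength=0.02, paper_lambda=True
    )
    azimuth = np.radians(20.0)
    spec = ssb.SingleComponentSpec(
        particle_diameter=80.0, fringe_resolution=3.8, fringe_azimuth=azimuth
    )
    image = ssb.single_component_image(spec, model, image_size=384, pixel_size=1.0)
    s0 = (np.cos(azimuth) / 3.8, np.sin(azimuth) / 3.8)
    delta = model.defocus * model.wavelength / spec.fringe_resolution  # 57.9 A
    return {
        "model": model,
        "spec": spec,
        "image": image,
        "s0": s0,
        "delta": delta,
        "unit": (np.cos(azimuth), np.sin(azimuth)),
    }


@pytest.fixture(scope="session")
def small_phantom():
    return ssb.make_chiral_phantom(48, 1.0, 18.0, seed=2)
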