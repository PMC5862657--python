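import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import ssbctf as ssb
from ssbctf.fourier import FourierImage, centered_fft2, freq_grid, nyquist_disc
from ssbctf.sideband import apply_real_ctf
from ssbctf.simulate import _sample_ft
from conftest import make_model


class TestSingleComponentImage:
    def test_real_and_hermitian(self, fig2_setup):
        img = fig2_setup["image"]
        assert np.isrealobj(img)
        assert FourierImage.from_real_image(img, 1.0).is_hermitian(1e-9)

    def test_sideband_disjoint_from_shadow(self, fig2_setup):
        # separation 2 dF lambda / d = 115.8 A exceeds the 80 A diameter
        f = fig2_setup
        assert 2 * f["delta"] > f["spec"].particle_diameter

    def test_zero_amplitude_is_pure_shadow(self):
        m = ssb.OpticalModel(voltage_kev=300.0, defocus=11000.0, paper_lambda=True)
        spec = ssb.SingleComponentSpec(
            particle_diameter=80.0, fringe_resolution=3.8, amplitude=0.0
        )
        img = ssb.single_component_image(spec, m, 384, 1.0)
        co = np.arange(384) - 192
        in_disc = np.hypot(co[:, None], co[None, :]) <= 40.0
        assert np.allclose(img[in_disc], -spec.shadow_depth * 0.0)
        assert np.all(img <= 0)

    def test_nyquist_violation_rejected(self):
        m = ssb.OpticalModel(voltage_kev=300.0, defocus=11000.0, paper_lambda=True)
        spec = ssb.SingleComponentSpec(particle_diameter=80.0, fringe_resolution=1.5)
        with pytest.raises(ValueError, match="Nyquist"):
            ssb.single_component_image(spec, m, 384, 1.0)

    def test_too_small_box_rejected(self):
        m = ssb.OpticalModel(voltage_kev=300.0, defocus=11000.0, paper_lambda=True)
        spec = ssb.SingleComponentSpec(particle_diameter=80.0, fringe_resolution=3.8)
        with pytest.raises(ValueError, match="box"):
            ssb.single_component_image(spec, m, 128, 1.0)


class TestForwardModel:
    def test_flat_sphere_reduces_to_ctf_times_projection(self, small_phantom):
        m = make_model(60.0)
        rot = Rotation.random(1, random_state=np.random.RandomState(5))[0].as_matrix()
        img = ssb.forward_image(small_phantom, rot, m, curvature="off")
        proj = ssb.project(small_phantom, rot)
        conv = apply_real_ctf(
            FourierImage.from_real_image(proj, 1.0), m
        ).to_real_image()
        assert np.abs(img - conv).max() < 1e-9 * conv.std()

    def test_output_real_for_random_orientations(self, small_phantom):
        m = make_model(120.0)
        for i, rot in enumerate(Rotation.random(3, random_state=np.random.RandomState(8))):
            img = ssb.forward_image(small_phantom, rot.as_matrix(), m, curvature="on")
            assert np.isrealobj(img)
            assert FourierImage.from_real_image(img, 1.0).is_hermitian(1e-8)

    def test_linear_in_phantom(self, small_phantom):
        m = make_model(120.0)
        rot = Rotation.random(1, random_state=np.random.RandomState(9))[0].as_matrix()
        other = ssb.Phantom3D(small_phantom.values[::-1].copy(), 1.0)
        a = ssb.forward_image(small_phantom, rot, m)
        b = ssb.forward_image(other, rot, m)
        both = ssb.Phantom3D(small_phantom.values + other.values, 1.0)
        ab = ssb.forward_image(both, rot, m)
        assert np.allclose(ab, a + b, atol=1e-9 * (np.abs(a) + np.abs(b)).max())

    def test_improper_rotation_rejected(self, small_phantom):
        m = make_model(120.0)
        with pytest.raises(ValueError, match="rotation"):
            ssb.forward_image(small_phantom, np.diag([1.0, 1.0, -1.0]), m)

    def test_curvature_argument_validated(self, small_phantom):
        m = make_model(120.0)
        with pytest.raises(ValueError, match="curvature"):
            ssb.forward_image(small_phantom, np.eye(3), m, curvature="sideways")

    def test_curved_samples_recovered_from_forward_image(self):
        # extract sideband samples from a curved image and compare with the
        # phantom transform probed at the same off-section positions
        from conftest import make_dataset, DIAMETER, LAMBDA

        phantom, images, records, models = make_dataset(
            seed=0, n_particles=1, curvature="on", defocus_range=(150.0, 150.0)
        )
        mask = ssb.MaskSpec.for_particle(DIAMETER)
        truth_vol = ssb.bandlimited_masked_truth(phantom.values, mask, 1.0)
        ft_os = ssb.Phantom3D(truth_vol, 1.0).oversampled_ft()
        p, q = ssb.sideband_correct(images[0], models[0], mask=mask, pixel_size=1.0)
        n = images[0].shape[0]
        sx, sy, s_mag, _ = freq_grid(n, 1.0)
        u = 2 * records[0].defocus * LAMBDA * s_mag / DIAMETER
        sel = nyquist_disc(n) & (u >= 1.5) & (s_mag <= 0.42)
        pts = np.stack([sx[sel], sy[sel], p.zstar[sel]])
        truth = _sample_ft(ft_os, records[0].orientation @ pts, 2 * 64 * 1.0)
        got = p.values[sel]
        strong = np.abs(truth) > np.percentile(np.abs(truth), 80)
        amp_err = np.abs(np.abs(got[strong]) / np.abs(truth[strong]) - 1)
        phase_err = np.degrees(np.abs(np.angle(got[strong] / truth[strong])))
        assert np.median(amp_err) < 0.03
        assert np.median(phase_err) < 5.0


class TestNoise:
    def test_zero_sd_is_identity(self):
        img = np.arange(16.0).reshape(4, 4)
        assert np.array_equal(ssb.add_noise(img, 0.0, seed=1), img)

    def test_variance_and_determinism(self):
        img = np.zeros((128, 128))
        noisy = ssb.add_noise(img, 2.5, seed=42)
        n = img.size
        se = 2.5**2 * np.sqrt(2.0 / n)
        assert abs(noisy.var() - 2.5**2) < 3 * se
        assert np.array_equal(noisy, ssb.add_noise(img, 2.5, seed=42))
        assert not np.array_equal(noisy, ssb.add_noise(img, 2.5, seed=43))

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            ssb.add_noise(np.zeros((4, 4)), -1.0, seed=0)


class TestChiralPhantom:
    def test_mirror_asymmetry(self):
        for seed in (0, 3, 11):
            ph = ssb.make_chiral_phantom(64, 1.0, 24.0, seed=seed)
            assert ph.mirror_correlation() < 0.9

    def test_nonnegative_and_bounded_support(self):
        ph = ssb.make_chiral_phantom(64, 1.0, 24.0, seed=1)
        assert ph.values.min() >= 0.0
        co = np.arange(64) - 32
        r = np.sqrt(
            co[:, None, None] ** 2 + co[None, :, None] ** 2 + co[None, None, :] ** 2
        )
        assert np.all(ph.values[r > 12.0] == 0.0)

    def test_deterministic_in_seed(self):
        a = ssb.make_chiral_phantom(48, 1.0, 20.0, seed=7)
        b = ssb.make_chiral_phantom(48, 1.0, 20.0, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_diameter_must_fit(self):
        with pytest.raises(ValueError):
            ssb.make_chiral_phantom(32, 1.0, 40.0, seed=0)
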