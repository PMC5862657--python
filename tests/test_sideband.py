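import numpy as np
import pytest
from scipy.integrate import quad
from scipy.spatial.transform import Rotation

import ssbctf as ssb
from ssbctf.fourier import FourierImage, centered_fft2, freq_grid, nyquist_disc
from ssbctf.sideband import (
    MaskSpec,
    SectorPlan,
    apply_complex_ctf,
    apply_real_ctf,
    fringe_centroid,
    mask_window,
    sideband_correct,
    soft_mask,
)
from conftest import make_model


def _bandlimited_random_image(n=64, seed=0):
    rng = np.random.default_rng(seed)
    ft = FourierImage.from_real_image(rng.normal(size=(n, n)), 1.0)
    ft.values[~nyquist_disc(n)] = 0.0
    return ft.to_real_image()


@pytest.fixture(scope="module")
def model():
    return make_model(150.0, amp_contrast=0.07)


class TestComplexCtfApplication:
    def test_p_then_q_is_identity(self, model):
        img = _bandlimited_random_image()
        ft = FourierImage.from_real_image(img, 1.0)
        out = apply_complex_ctf(
            apply_complex_ctf(ft, model, 0.3, "P"), model, 0.3, "Q"
        )
        assert np.abs(out.values - ft.values).max() < 1e-9 * np.abs(ft.values).max()

    @pytest.mark.parametrize("boundary", [0.0, np.pi / 4, 1.1])
    def test_p_plus_q_equals_real_ctf(self, model, boundary):
        img = _bandlimited_random_image(seed=3)
        ft = FourierImage.from_real_image(img, 1.0)
        p = apply_complex_ctf(ft, model, boundary, "P").values
        q = apply_complex_ctf(ft, model, boundary, "Q").values
        r = apply_real_ctf(ft, model).values
        assert np.abs(p + q - r).max() < 1e-10 * np.abs(r).max()

    @pytest.mark.parametrize("side", ["P", "Q"])
    def test_corrected_image_is_real(self, model, side):
        img = _bandlimited_random_image(seed=5)
        ft = FourierImage.from_real_image(img, 1.0)
        for boundary in (0.0, np.pi / 2, 0.7):
            out = apply_complex_ctf(ft, model, boundary, side)
            assert out.is_hermitian(1e-9)
            real_img = np.fft.fftshift(
                np.fft.ifft2(np.fft.ifftshift(out.values))
            )
            assert np.abs(real_img.imag).max() < 1e-9 * real_img.real.std()

    def test_dc_untouched(self, model):
        img = _bandlimited_random_image(seed=6) + 5.0
        ft = FourierImage.from_real_image(img, 1.0)
        out = apply_complex_ctf(ft, model, 0.0, "P")
        n = ft.n
        assert out.values[n // 2, n // 2] == pytest.approx(ft.values[n // 2, n // 2])

    def test_non_hermitian_input_rejected(self, model):
        bad = FourierImage(np.random.default_rng(0).normal(size=(16, 16)) + 1j, 1.0)
        with pytest.raises(ValueError, match="Hermitian"):
            apply_complex_ctf(bad, model, 0.0, "P")


class TestSoftMask:
    def test_hard_disc_at_zero_edge(self):
        img = np.ones((64, 64))
        out = soft_mask(img, None, 30.0, 0.0, 1.0)
        co = np.arange(64) - 32
        r = np.hypot(co[:, None], co[None, :])
        assert np.array_equal(out, (r <= 15.0).astype(float))

    @pytest.mark.parametrize("profile", ["gaussian", "cosine"])
    def test_flux_matches_radial_quadrature(self, profile):
        # window applied to a unit image: total flux equals the 2D integral
        # of the radial profile (independent 1D quadrature oracle)
        from scipy.special import erfc

        diameter, edge = 40.0, 8.0
        out = soft_mask(np.ones((128, 128)), None, diameter, edge, 1.0, profile=profile)
        if profile == "cosine":
            def w(r):
                t = np.clip((r - diameter / 2) / edge, 0.0, 1.0)
                return 0.5 * (1 + np.cos(np.pi * t))
        else:
            def w(r):
                return 0.5 * erfc((r - diameter / 2 - edge / 2) / (np.sqrt(2) * edge / 4))
        flux, _ = quad(lambda r: w(r) * 2 * np.pi * r, 0, 64.0)
        assert out.sum() == pytest.approx(flux, rel=5e-3)

    def test_idempotent_on_plateau(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(64, 64))
        once = soft_mask(img, None, 30.0, 6.0, 1.0)
        twice = soft_mask(once, None, 30.0, 6.0, 1.0)
        co = np.arange(64) - 32
        plateau = np.hypot(co[:, None], co[None, :]) <= 10.0
        assert np.allclose(once[plateau], img[plateau])
        assert np.allclose(twice[plateau], once[plateau])

    def test_mask_exceeding_image_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            soft_mask(np.ones((32, 32)), None, 40.0, 10.0, 1.0)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            MaskSpec(diameter=-1.0, edge_width=1.0)
        with pytest.raises(ValueError):
            MaskSpec(diameter=10.0, edge_width=1.0, profile="boxcar")


class TestSectorPlan:
    def test_default_covers_all_azimuths(self):
        plan = SectorPlan()
        assert plan.n_sectors == 8

    def test_uncovered_plan_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            SectorPlan(rotations=(0.0,), keep_margin=np.pi / 8)

    def test_single_sector_plan(self):
        plan = SectorPlan.single(np.radians(22.0))
        assert plan.n_sectors == 2


class TestSidebandCorrect:
    def test_zero_image_gives_zero_samples(self, model):
        p, q = sideband_correct(np.zeros((64, 64)), model, pixel_size=1.0,
                                mask=MaskSpec.for_particle(24.0))
        assert np.all(p.amp == 0) and np.all(q.amp == 0)

    def test_zstar_structure(self, model):
        img = _bandlimited_random_image()
        p, q = sideband_correct(img, model, pixel_size=1.0)
        n = 64
        assert np.allclose(p.zstar, -q.zstar)
        _, _, s_mag, _ = freq_grid(n, 1.0)
        disc = nyquist_disc(n)
        expected = 0.5 * model.wavelength * s_mag**2
        assert np.allclose(np.abs(p.zstar[disc]), expected[disc], atol=1e-15)
        # odd under Friedel inversion: zstar(-s) = -zstar(s)
        flipped = np.roll(p.zstar[::-1, ::-1], (1, 1), axis=(0, 1))
        inner = nyquist_disc(n) & np.roll(nyquist_disc(n)[::-1, ::-1], (1, 1), (0, 1))
        assert np.allclose(p.zstar[inner], -flipped[inner], atol=1e-15)

    def test_warns_below_separation_threshold(self):
        m = make_model(20.0)
        with pytest.warns(UserWarning, match="threshold"):
            sideband_correct(np.zeros((64, 64)), m, pixel_size=1.0,
                             particle_diameter=24.0)

    def test_sector_boundary_robustness(self):
        # a fringe 1 degree from a boundary axis must be recovered with the
        # same fidelity as one in the middle of a sector
        m = ssb.OpticalModel(voltage_kev=300.0, defocus=11000.0, paper_lambda=True)
        ratios = {}
        for name, az in [("near_boundary", np.radians(1.0)),
                         ("sector_centre", np.radians(22.5))]:
            spec = ssb.SingleComponentSpec(
                particle_diameter=80.0, fringe_resolution=3.8, fringe_azimuth=az
            )
            img = ssb.single_component_image(spec, m, 384, 1.0)
            p, q = sideband_correct(img, m, mask=MaskSpec.for_particle(80.0),
                                    pixel_size=1.0)
            n = 384
            kx = round(np.cos(az) / 3.8 * n)
            ky = round(np.sin(az) / 3.8 * n)
            co = (np.arange(n) - n // 2) * 1.0
            x, y = co[:, None], co[None, :]
            disc = np.hypot(x, y) <= 40.0
            s0 = (np.cos(az) / 3.8, np.sin(az) / 3.8)
            o_plus = disc * 0.5 * np.exp(1j * 2 * np.pi * (s0[0] * x + s0[1] * y))
            truth = np.abs(centered_fft2(o_plus)[n // 2 + kx, n // 2 + ky])
            amp = max(p.amp[n // 2 + kx, n // 2 + ky], q.amp[n // 2 + kx, n // 2 + ky])
            ratios[name] = amp / truth
        assert ratios["near_boundary"] == pytest.approx(
            ratios["sector_centre"], rel=0.01
        )

    def test_flat_sphere_degeneracy_p_equals_q(self, small_phantom):
        # with curvature off the two sideband extractions sample the same
        # (central) section; in the separated band, where the wrong-sideband
        # ghost is masked away, they must agree
        m = make_model(150.0)
        rot = Rotation.random(1, random_state=np.random.RandomState(3))[0].as_matrix()
        img = ssb.forward_image(small_phantom, rot, m, curvature="off",
                                image_size=128)
        p, q = sideband_correct(img, m, mask=MaskSpec.for_particle(18.0),
                                pixel_size=1.0)
        gp, gq = p.values, q.values
        _, _, s_mag, _ = freq_grid(128, 1.0)
        u = 2 * 150.0 * m.wavelength * s_mag / 18.0
        band = nyquist_disc(128) & (u >= 1.3) & (s_mag <= 0.42)
        num = np.abs(gp - gq)[band] ** 2
        den = np.abs(gp + gq)[band] ** 2 / 4
        assert np.sqrt(num.sum() / den.sum()) < 0.15


class TestRelocalization:
    def test_raw_sideband_sits_at_delocalisation_distance(self, fig2_setup):
        f = fig2_setup
        cx, cy = fringe_centroid(f["image"], f["s0"], 1.0)
        assert np.hypot(cx, cy) == pytest.approx(f["delta"], abs=1.0)

    def test_correct_side_relocalises_to_centre(self, fig2_setup):
        f = fig2_setup
        ft = FourierImage.from_real_image(f["image"], 1.0)
        boundary = np.radians(20.0 - 90.0)  # fringe far from the boundary
        corrected = apply_complex_ctf(ft, f["model"], boundary, "Q").to_real_image()
        cx, cy = fringe_centroid(corrected, f["s0"], 1.0)
        assert np.hypot(cx, cy) < 1.0

    def test_wrong_side_doubles_the_displacement(self, fig2_setup):
        f = fig2_setup
        ft = FourierImage.from_real_image(f["image"], 1.0)
        boundary = np.radians(20.0 - 90.0)
        wrong = apply_complex_ctf(ft, f["model"], boundary, "P").to_real_image()
        assert ssb.relocalization_distance(
            f["image"], wrong, f["s0"], 1.0
        ) == pytest.approx(f["delta"], abs=1.5)
        cx, cy = fringe_centroid(wrong, f["s0"], 1.0)
        assert np.hypot(cx, cy) == pytest.approx(2 * f["delta"], abs=1.5)

    def test_centroid_undefined_without_power(self):
        with pytest.raises(ValueError, match="power"):
            fringe_centroid(np.zeros((64, 64)), (0.25, 0.0), 1.0)
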