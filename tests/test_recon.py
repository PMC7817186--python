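import numpy as np
import pytest
from scipy import ndimage
from scipy.special import spherical_jn

from istomo.io import Tomogram, ValidationError, VolumeMetadata
from istomo.phantom import (forward_scatter, illumination_directions,
                            make_sphere_phantom, synthesize_hologram)
from istomo.recon import (CarrierOverlapError, compute_resolution,
                          incident_plane_wave, map_to_spectrum,
                          regularize_nonneg, retrieve_field, ri_to_density,
                          rytov_field)

LAM = 532.0
N_MED = 1.337


# ---------------------------------------------------------------------
# field retrieval
# ---------------------------------------------------------------------


class TestRetrieveField:
    PITCH = (200.0, 200.0)
    CARRIER = (1.0 / 1600.0, 1.0 / 1600.0)

    def test_plane_wave_reference_only(self):
        """A hologram of a unit plane wave demodulates to amplitude 1, phase 0."""
        field = np.ones((64, 64), complex)
        holo = synthesize_hologram(field, self.CARRIER, self.PITCH)
        rec = retrieve_field(holo, self.CARRIER, self.PITCH)
        assert np.allclose(np.abs(rec), 1.0, atol=1e-6)
        phase = np.angle(rec)
        assert np.allclose(phase - phase.mean(), 0.0, atol=1e-6)

    def test_gaussian_phase_round_trip(self):
        """Synthesize-then-retrieve recovers a smooth phase to < 1e-3 rad RMS."""
        yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        phi = 1.2 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 8**2))
        field = np.exp(1j * phi)
        holo = synthesize_hologram(field, self.CARRIER, self.PITCH)
        rec = retrieve_field(holo, self.CARRIER, self.PITCH)
        err = np.angle(rec * np.exp(-1j * phi))
        assert np.sqrt(np.mean(err**2)) < 1e-3

    def test_zero_carrier_rejected(self):
        holo = np.ones((32, 32))
        with pytest.raises(CarrierOverlapError):
            retrieve_field(holo, (0.0, 0.0), self.PITCH)


class TestRytovField:
    def test_identity(self):
        f = np.exp(1j * 0.3) * np.ones((16, 16))
        psi = rytov_field(f, f)
        assert np.allclose(psi, 0.0, atol=1e-12)

    def test_small_phase_definition(self):
        yy, xx = np.meshgrid(np.arange(32), np.arange(32), indexing="ij")
        phi = 0.5 * np.sin(2 * np.pi * yy / 32) * np.cos(2 * np.pi * xx / 32)
        inc = np.ones((32, 32), complex)
        psi = rytov_field(inc * np.exp(1j * phi), inc)
        assert np.allclose(psi.imag, phi, atol=1e-9)
        assert np.allclose(psi.real, 0.0, atol=1e-12)

    def test_unwraps_multi_cycle_phase(self):
        """A smooth phase spanning several cycles is recovered unwrapped."""
        yy, xx = np.meshgrid(np.arange(64), np.arange(64), indexing="ij")
        phi = 9.0 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 10**2))
        inc = np.ones((64, 64), complex)
        psi = rytov_field(inc * np.exp(1j * phi), inc)
        assert np.allclose(psi.imag, phi, atol=1e-6)

    def test_zero_incident_rejected(self):
        with pytest.raises(ZeroDivisionError):
            rytov_field(np.ones((4, 4), complex), np.zeros((4, 4), complex))


# ---------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------


class TestForwardScatter:
    def test_zero_contrast_scatters_nothing(self):
        tom = Tomogram(np.full((32, 32, 32), N_MED, np.float32),
                       pitch=(100.0,) * 3, medium_ri=N_MED)
        meta = VolumeMetadata(n_illuminations=3)
        hs = forward_scatter(tom, meta)
        for i in range(3):
            psi = rytov_field(hs.fields[i], incident_plane_wave(hs, i))
            assert np.abs(psi).max() < 1e-9

    def test_thin_slab_phase_delay(self):
        """Normal-incidence transmission through a thin slab delays the phase
        by 2 pi (n^2 - n_m^2)/(2 n_m) d / lambda ~ 2 pi dn d / lambda."""
        dn, d_slices, pitch = 0.002, 3, 100.0
        vals = np.full((64, 64, 64), N_MED, np.float32)
        vals[30:33] = N_MED + dn
        tom = Tomogram(vals, pitch=(pitch,) * 3, medium_ri=N_MED)
        hs = forward_scatter(tom, VolumeMetadata(n_illuminations=1))
        psi = rytov_field(hs.fields[0], incident_plane_wave(hs, 0))
        expected = 2 * np.pi * dn * d_slices * pitch / LAM
        assert psi.imag.mean() == pytest.approx(expected, rel=2e-3)

    def test_sphere_spectrum_matches_closed_form(self):
        """Cap samples agree with the analytic transform of a Gaussian-
        smoothed ball to within 2% RMS."""
        pitch, dn, R, sig = 100.0, 0.01, 800.0, 1.2
        zz, yy, xx = np.meshgrid(*[np.arange(64)] * 3, indexing="ij",
                                 sparse=True)
        c = 31.5
        ball = (((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2)
                <= (R / pitch) ** 2).astype(float)
        ball = ndimage.gaussian_filter(ball, sig)
        tom = Tomogram((N_MED + dn * ball).astype(np.float32),
                       pitch=(pitch,) * 3, medium_ri=N_MED)
        meta = VolumeMetadata(n_illuminations=5, na_illumination=1.0,
                              na_detection=1.2)
        hs = forward_scatter(tom, meta)

        nu_m = N_MED / LAM
        k0sq = (2 * np.pi / LAM) ** 2
        q = np.fft.fftfreq(64, d=pitch)
        QY, QX = np.meshgrid(q, q, indexing="ij")
        for i, s in enumerate(hs.directions):
            psi = rytov_field(hs.fields[i], incident_plane_wave(hs, i))
            psi_hat = np.fft.fft2(psi) * pitch**2
            nu_i = nu_m * s
            PY, PX = QY + nu_i[1], QX + nu_i[2]
            p2 = PY**2 + PX**2
            nu_z = np.sqrt(np.maximum(nu_m**2 - p2, 0.0))
            kz = nu_z - nu_i[0]
            ok = (p2 < nu_m**2) & (p2 <= (1.2 / LAM) ** 2) & (np.abs(kz) <= 0.5 / pitch)
            measured = 4 * np.pi * nu_z[ok] * psi_hat[ok] / 1j
            K = np.sqrt(QY[ok] ** 2 + QX[ok] ** 2 + kz[ok] ** 2)
            x = 2 * np.pi * np.maximum(K, 1e-9) * R
            ball_ft = 4 / 3 * np.pi * R**3 * np.where(
                x < 1e-6, 1.0, 3 * spherical_jn(1, x) / x)
            gauss = np.exp(-2 * np.pi**2 * (sig * pitch) ** 2 * K**2)
            phase = np.exp(-2j * np.pi * (kz[ok] * (c - 32) * pitch
                                          + (QY[ok] + QX[ok]) * c * pitch))
            analytic = k0sq * 2 * N_MED * dn * ball_ft * gauss * phase
            rel = (np.sqrt(np.mean(np.abs(measured - analytic) ** 2))
                   / np.sqrt(np.mean(np.abs(analytic) ** 2)))
            assert rel < 0.02

    def test_high_contrast_flagged(self):
        vals = np.full((16, 16, 16), N_MED, np.float32)
        vals[8] = N_MED + 0.1
        tom = Tomogram(vals, pitch=(100.0,) * 3, medium_ri=N_MED)
        with pytest.raises(ValidationError):
            forward_scatter(tom, VolumeMetadata(n_illuminations=1), strict=True)

    def test_illumination_layout(self):
        dirs = illumination_directions(VolumeMetadata(n_illuminations=49),
                                       N_MED)
        assert dirs.shape == (49, 3)
        np.testing.assert_allclose(np.linalg.norm(dirs, axis=1), 1.0)
        np.testing.assert_allclose(dirs[0], (1.0, 0.0, 0.0))
        # cone angle set by the illumination NA
        sin_t = np.linalg.norm(dirs[1:, 1:], axis=1)
        np.testing.assert_allclose(sin_t, 1.2 / N_MED, rtol=1e-12)


# ---------------------------------------------------------------------
# spectrum mapping and regularization
# ---------------------------------------------------------------------


@pytest.fixture(scope="module")
def sphere_holograms():
    tom, support = make_sphere_phantom(shape=(48, 48, 48), pitch_nm=100.0,
                                       radius_nm=700.0, delta_n=0.015)
    meta = VolumeMetadata(n_illuminations=13, na_illumination=1.2,
                          na_detection=1.2)
    return tom, support, forward_scatter(tom, meta)


class TestMapToSpectrum:
    def test_dc_maps_to_origin(self, sphere_holograms):
        tom, _, hs = sphere_holograms
        one = map_to_spectrum(
            type(hs)(fields=hs.fields[:1], directions=hs.directions[:1],
                     wavelength_nm=hs.wavelength_nm, pitch_nm=hs.pitch_nm,
                     pitch_z_nm=hs.pitch_z_nm, n_z=hs.n_z,
                     medium_ri=hs.medium_ri, na_detection=hs.na_detection))
        assert one.occupancy[0, 0, 0] > 0
        # DC value equals the total scattering potential (fftn convention)
        k0sq = (2 * np.pi / LAM) ** 2
        V = k0sq * (tom.values.astype(float) ** 2 - tom.medium_ri**2)
        got = one.averaged()[0, 0, 0]
        assert got.real == pytest.approx(V.sum(), rel=0.01)

    def test_occupancy_grows_with_illuminations(self, sphere_holograms):
        _, _, hs = sphere_holograms
        counts = []
        for n in (1, 5, 13):
            sub = type(hs)(fields=hs.fields[:n], directions=hs.directions[:n],
                           wavelength_nm=hs.wavelength_nm, pitch_nm=hs.pitch_nm,
                           pitch_z_nm=hs.pitch_z_nm, n_z=hs.n_z,
                           medium_ri=hs.medium_ri, na_detection=hs.na_detection)
            counts.append(int(np.count_nonzero(map_to_spectrum(sub).occupancy)))
        assert counts[0] < counts[1] < counts[2]

    def test_point_scatterer_localized(self):
        """Reconstruction of a point-like scatterer peaks at its position."""
        vals = np.full((48, 48, 48), N_MED, np.float32)
        loc = (22, 27, 19)
        vals[loc] = N_MED + 0.01
        tom = Tomogram(vals, pitch=(100.0,) * 3, medium_ri=N_MED)
        meta = VolumeMetadata(n_illuminations=13, na_illumination=1.2,
                              na_detection=1.2)
        rec = regularize_nonneg(map_to_spectrum(forward_scatter(tom, meta)),
                                iterations=30)
        peak = np.unravel_index(np.argmax(rec.contrast), rec.shape)
        assert max(abs(p - l) for p, l in zip(peak, loc)) <= 1


class TestRegularizeNonneg:
    def test_fully_sampled_nonneg_is_fixed_point(self, rng):
        """With every voxel measured and a non-negative object the first
        inversion is already the fixed point."""
        V = np.abs(rng.random((12, 12, 12)))
        S = np.fft.fftn(V)
        from istomo.recon import SpectrumAccumulator

        acc = SpectrumAccumulator(spectrum=S, occupancy=np.ones(V.shape),
                                  pitch_nm=(100.0,) * 3, medium_ri=N_MED,
                                  wavelength_nm=LAM)
        rec0 = regularize_nonneg(acc, iterations=0)
        rec50 = regularize_nonneg(acc, iterations=50)
        np.testing.assert_allclose(rec50.values, rec0.values, atol=1e-6)

    def test_nonnegativity_enforced(self, sphere_holograms):
        _, _, hs = sphere_holograms
        rec = regularize_nonneg(map_to_spectrum(hs), iterations=20)
        assert rec.contrast.min() >= -1e-9

    def test_regularization_reduces_support_rmse(self, sphere_holograms):
        tom, support, hs = sphere_holograms
        acc = map_to_spectrum(hs)
        err0 = regularize_nonneg(acc, iterations=0).values - tom.values
        err1 = regularize_nonneg(acc, iterations=50).values - tom.values
        rmse0 = np.sqrt(np.mean(err0[support] ** 2))
        rmse1 = np.sqrt(np.mean(err1[support] ** 2))
        assert rmse1 < rmse0

    def test_fourier_fidelity(self, sphere_holograms):
        """Measured-frequency voxels of the regularized spectrum stay at the
        measured values."""
        _, _, hs = sphere_holograms
        acc = map_to_spectrum(hs)
        rec = regularize_nonneg(acc, iterations=7)
        k0sq = (2 * np.pi / LAM) ** 2
        nz = acc.spectrum.shape[0]
        V = np.zeros((nz,) + rec.shape[1:])
        V[:rec.shape[0]] = k0sq * (rec.values.astype(float) ** 2
                                   - rec.medium_ri**2)
        # one more fidelity projection must not change the measured voxels
        # beyond the final object-space clamp's effect
        S = np.fft.fftn(V)
        meas = acc.measured
        resid = np.abs(S[meas] - acc.averaged()[meas])
        scale = np.abs(acc.averaged()[meas]).max()
        assert np.median(resid) / scale < 0.05


class TestAxialElongation:
    def test_point_spread_longer_axially(self):
        """The missing cone elongates a point reconstruction along z."""
        vals = np.full((48, 48, 48), N_MED, np.float32)
        vals[24, 24, 24] = N_MED + 0.01
        tom = Tomogram(vals, pitch=(100.0,) * 3, medium_ri=N_MED)
        meta = VolumeMetadata(n_illuminations=13, na_illumination=1.2,
                              na_detection=1.2)
        rec = regularize_nonneg(map_to_spectrum(forward_scatter(tom, meta)),
                                iterations=0)
        c = rec.contrast
        peak = np.unravel_index(np.argmax(c), c.shape)
        prof_z = c[:, peak[1], peak[2]]
        prof_x = c[peak[0], peak[1], :]

        def fwhm(profile, center):
            half = profile[center] / 2
            above = np.where(profile >= half)[0]
            return above.max() - above.min() + 1

        assert fwhm(prof_z, peak[0]) > fwhm(prof_x, peak[2])


# ---------------------------------------------------------------------
# resolution and densitometry
# ---------------------------------------------------------------------


class TestResolution:
    def test_symmetric_na_lateral(self):
        meta = VolumeMetadata(na_illumination=1.2, na_detection=1.2)
        rep = compute_resolution(meta, medium_ri=N_MED)
        assert rep.lateral_nm == pytest.approx(532.0 / 4.8, abs=0.05)
        assert rep.lateral_nm == pytest.approx(110.8, abs=0.05)

    def test_detection_only_lateral(self):
        meta = VolumeMetadata(na_illumination=1e-6, na_detection=1.2)
        rep = compute_resolution(meta, medium_ri=N_MED)
        assert rep.lateral_nm == pytest.approx(221.7, abs=0.1)

    def test_axial_exceeds_lateral_and_variants_differ(self):
        meta = VolumeMetadata(na_illumination=1.1, na_detection=1.2)
        two = compute_resolution(meta, N_MED, axial_formula="two_cone")
        one = compute_resolution(meta, N_MED, axial_formula="single_cone")
        assert two.axial_nm > two.lateral_nm
        assert one.axial_nm > two.axial_nm

    def test_periods_grow_as_na_shrinks(self):
        meta = lambda na: VolumeMetadata(na_illumination=na, na_detection=na)
        nas = [1.2, 0.9, 0.6, 0.3]
        reps = [compute_resolution(meta(na), N_MED) for na in nas]
        lat = [r.lateral_nm for r in reps]
        ax = [r.axial_nm for r in reps]
        assert lat == sorted(lat) and ax == sorted(ax)

    def test_na_above_medium_rejected(self):
        meta = VolumeMetadata(na_illumination=1.4, na_detection=1.2)
        with pytest.raises(ValidationError):
            compute_resolution(meta, medium_ri=N_MED)


class TestRiToDensity:
    PITCH = (218.5,) * 3

    def make(self, dn):
        vals = np.full((4, 4, 4), N_MED + dn, np.float32)
        return Tomogram(vals, pitch=self.PITCH, medium_ri=N_MED)

    def test_zero_contrast(self):
        assert ri_to_density(self.make(0.0)).values.max() == 0.0

    def test_reference_conversion(self):
        """dn = 0.0185 at alpha = 0.185 mL/g is exactly 100 fg/um^3."""
        d = ri_to_density(self.make(0.0185), alpha_ml_per_g=0.185)
        np.testing.assert_allclose(d.values, 100.0, rtol=1e-5)

    def test_linearity(self):
        d = ri_to_density(self.make(0.00185), alpha_ml_per_g=0.185)
        np.testing.assert_allclose(d.values, 10.0, rtol=1e-4)

    def test_negative_contrast_clamped(self):
        d = ri_to_density(self.make(-0.01))
        assert d.values.min() == 0.0
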