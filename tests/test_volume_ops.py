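"""Cylindrical resampling, lathing, symmetrization, azimuthal spectra,
radial profiles and FSC."""

import numpy as np
import pytest

from motorsym.cylinder import (
    azimuthal_power_spectrum,
    detect_symmetry,
    estimate_feature_radius,
    lathe,
    radial_profile,
    resample_cylindrical,
    symmetrize,
    to_cartesian,
)
from motorsym.fourier import FSC_MAP_MODEL, fsc, lowpass, resolution_at
from motorsym.phantom import Annulus, TubeComponent, MotorPhantomSpec, make_motor_phantom
from motorsym.volume import Volume

from conftest import single_ring_phantom


def gaussian_tube(box=64, voxel=2.0, radius=30.0, sigma=20.0):
    """Wide, smooth radially symmetric tube (gentle enough for trilinear
    interpolation to track)."""
    ax = (np.arange(box) - box / 2) * voxel
    r = np.hypot(ax[:, None], ax[None, :])
    prof = np.exp(-((r - radius) ** 2) / (2 * sigma**2))
    return Volume(np.repeat(prof[:, :, None], box, axis=2), voxel)


class TestResampleCylindrical:
    def test_rejects_non_power_of_two_theta(self):
        with pytest.raises(ValueError, match="power of two"):
            resample_cylindrical(gaussian_tube(), 300)
        with pytest.raises(ValueError, match="power of two"):
            resample_cylindrical(gaussian_tube(), 128)

    def test_radially_symmetric_tube_theta_independent(self):
        cmap = resample_cylindrical(gaussian_tube(), 256)
        vals = cmap.values[2:30, :, 32]  # interior radii, central slice
        spread = np.nanmax(vals, axis=1) - np.nanmin(vals, axis=1)
        # trilinear interpolation of a sigma = 10-voxel tube leaves a
        # theta-dependent residual of a few 1e-3 of the peak
        assert np.all(spread <= 5e-3 * np.nanmax(vals))

    def test_off_axis_blob_peaks_at_its_azimuth(self):
        theta0 = 1.2
        box, voxel, r0 = 64, 2.0, 40.0
        ax = (np.arange(box) - 32) * voxel
        d2 = (
            (ax[:, None, None] - r0 * np.cos(theta0)) ** 2
            + (ax[None, :, None] - r0 * np.sin(theta0)) ** 2
            + (ax[None, None, :]) ** 2
        )
        v = Volume(np.exp(-d2 / (2 * 4.0**2)), voxel)
        cmap = resample_cylindrical(v, 256)
        ir = int(round(r0 / voxel))
        prof = np.nanmean(cmap.values[ir], axis=1)
        t_peak = cmap.theta[np.argmax(prof)]
        dtheta = 2 * np.pi / 256
        assert abs(np.angle(np.exp(1j * (t_peak - theta0)))) <= dtheta

    def test_round_trip_on_smooth_map(self, rng):
        noise = Volume(rng.normal(0, 1, (64, 64, 64)), 2.0)
        smooth = lowpass(noise, 24.0)
        cmap = resample_cylindrical(smooth, 256)
        back = to_cartesian(cmap, 64)
        ax = np.arange(64) - 32
        inside = np.hypot(ax[:, None], ax[None, :]) < 30
        err = (back.grid - smooth.grid)[inside, :]
        assert np.sqrt(np.mean(err**2)) < 0.02 * smooth.grid.std()


class TestLathe:
    def test_idempotent(self, c17_phantom):
        once = lathe(c17_phantom)
        twice = lathe(once)
        rms = np.sqrt(np.mean((twice.grid - once.grid) ** 2))
        assert rms <= 0.01 * once.grid.std()

    def test_output_has_no_azimuthal_power(self, c17_phantom):
        lv = lathe(c17_phantom)
        s = azimuthal_power_spectrum(
            resample_cylindrical(lv, 256), Annulus(30, 58, -14, 14)
        )
        assert s.ac_power <= 1e-3 * s.dc_power
        assert not detect_symmetry(s).called

    def test_matches_high_order_symmetrization(self):
        """Lathing equals the large-n limit of Cn symmetrization (n=360)."""
        v = single_ring_phantom(17, radius=30.0, box_size=48)
        c360 = symmetrize(v, 360)
        lv = lathe(v)
        rms = np.sqrt(np.mean((c360.grid - lv.grid) ** 2))
        assert rms <= 0.05 * v.grid.std()


class TestSymmetrize:
    def test_n1_is_identity(self, c17_phantom):
        assert np.array_equal(symmetrize(c17_phantom, 1).grid, c17_phantom.grid)

    def test_idempotent_within_tolerance(self, c17_phantom):
        once = symmetrize(c17_phantom, 17)
        twice = symmetrize(once, 17)
        rms = np.sqrt(np.mean((twice.grid - once.grid) ** 2))
        assert rms <= 0.01 * once.grid.std()

    def test_c17_phantom_unchanged_by_c17_symmetrization(self, c17_phantom):
        sym = symmetrize(c17_phantom, 17)
        rms = np.sqrt(np.mean((sym.grid - c17_phantom.grid) ** 2))
        assert rms <= 0.02 * c17_phantom.grid.std()

    def test_rejects_bad_order(self, c17_phantom):
        with pytest.raises(ValueError):
            symmetrize(c17_phantom, 0)

    def test_commutes_with_lathe(self, c17_phantom):
        a = lathe(symmetrize(c17_phantom, 5))
        b = symmetrize(lathe(c17_phantom), 5)
        rms = np.sqrt(np.mean((a.grid - b.grid) ** 2))
        assert rms <= 0.02 * c17_phantom.grid.std()


class TestAzimuthalSpectrum:
    def test_pure_cos17_pattern_concentrates_at_m17(self):
        box, voxel = 64, 2.0
        ax = (np.arange(box) - 32) * voxel
        r = np.hypot(ax[:, None], ax[None, :])
        theta = np.arctan2(ax[None, :], ax[:, None])
        ring = np.exp(-((r - 40.0) ** 2) / (2 * 16.0)) * np.cos(17 * theta)
        v = Volume(np.repeat(ring[:, :, None], box, axis=2), voxel)
        s = azimuthal_power_spectrum(
            resample_cylindrical(v, 256), Annulus(28, 52, -20, 20)
        )
        assert s.power[17] > 0.99
        assert np.argmax(s.power[1:]) + 1 == 17

    def test_normalized_over_nonzero_harmonics(self, c17_phantom):
        s = azimuthal_power_spectrum(
            resample_cylindrical(c17_phantom, 256), Annulus(30, 58, -14, 14)
        )
        assert s.power[1:].sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(s.power >= 0)

    def test_empty_annulus_rejected(self, c17_phantom):
        cmap = resample_cylindrical(c17_phantom, 256)
        with pytest.raises(ValueError, match="annulus"):
            azimuthal_power_spectrum(cmap, Annulus(200, 300, -10, 10))


class TestDetectSymmetry:
    def test_noise_only_volume_gives_no_call(self, rng):
        v = Volume(rng.normal(0, 1, (64, 64, 64)), 2.0)
        s = azimuthal_power_spectrum(
            resample_cylindrical(v, 256), Annulus(30, 58, -30, 30)
        )
        call = detect_symmetry(s)
        assert not call.called
        assert call.confidence < 2.0

    def test_rejects_low_m_min(self, c17_phantom):
        s = azimuthal_power_spectrum(
            resample_cylindrical(c17_phantom, 256), Annulus(30, 58, -14, 14)
        )
        with pytest.raises(ValueError):
            detect_symmetry(s, m_min=1)


class TestRadialProfile:
    def test_tube_profile_peaks_at_tube_radius(self):
        spec = MotorPhantomSpec(
            [TubeComponent(radius=40.0, z_center=0.0, height=40.0)],
            box_size=64, voxel_size=2.0,
        )
        prof = radial_profile(make_motor_phantom(spec), (-16, 16))
        assert abs(prof.r[np.argmax(prof.density)] - 40.0) <= 2.0

    def test_uniform_box_gives_flat_profile(self):
        v = Volume(np.full((48, 48, 48), 2.5), 2.0)
        prof = radial_profile(v, (-20, 20))
        assert np.nanmax(np.abs(prof.density - 2.5)) < 1e-9

    def test_nested_tubes_resolve_two_maxima(self):
        spec = MotorPhantomSpec(
            [
                TubeComponent(radius=24.0, z_center=0.0, height=40.0, wall_sigma=3.0),
                TubeComponent(radius=48.0, z_center=0.0, height=40.0, wall_sigma=3.0),
            ],
            box_size=64, voxel_size=2.0,
        )
        prof = radial_profile(make_motor_phantom(spec), (-16, 16))
        inner = estimate_feature_radius(prof, (14, 34))
        outer = estimate_feature_radius(prof, (38, 58))
        assert inner == pytest.approx(24.0, abs=2.0)
        assert outer == pytest.approx(48.0, abs=2.0)

    def test_empty_z_range_rejected(self, c17_phantom):
        with pytest.raises(ValueError, match="z_range"):
            radial_profile(c17_phantom, (200, 300))


class TestFeatureRadius:
    @pytest.mark.parametrize("r_true", [62.0, 51.0])
    def test_collar_radius_recovered_within_one_angstrom(self, r_true):
        from motorsym.phantom import collar_phantom

        v = collar_phantom(r_true, seed=20231009, snr=1.0)
        prof = radial_profile(v, (-20, 20))
        r_est = estimate_feature_radius(prof, (r_true - 20, r_true + 20))
        assert r_est == pytest.approx(r_true, abs=1.0)

    def test_window_without_peak_returns_not_found(self):
        from motorsym.phantom import collar_phantom

        v = collar_phantom(62.0, seed=1, snr=0)
        prof = radial_profile(v, (-20, 20))
        assert estimate_feature_radius(prof, (5.0, 25.0)) is None


class TestLowpass:
    def test_near_nyquist_cutoff_approaches_identity(self, c17_phantom):
        # the identity limit of a low-pass is the finest admissible cutoff
        # (just above Nyquist); the phantom's Gaussians carry almost no
        # power out there
        out = lowpass(c17_phantom, 4.2)
        assert np.abs(out.grid - c17_phantom.grid).max() < 0.05 * c17_phantom.grid.std()

    def test_mean_density_preserved(self, c17_phantom):
        out = lowpass(c17_phantom, 15.0)
        assert out.grid.mean() == pytest.approx(c17_phantom.grid.mean(), rel=1e-9)

    def test_white_noise_power_beyond_cutoff_suppressed(self, rng):
        v = Volume(rng.normal(0, 1, (64, 64, 64)), 2.0)
        out = lowpass(v, 10.0)
        k = np.fft.fftfreq(64, d=2.0)
        kr = np.sqrt(
            k[:, None, None] ** 2 + k[None, :, None] ** 2 + k[None, None, :] ** 2
        )
        beyond = kr > 1.0 / 10.0 + 1.0 / (64 * 2.0)
        p_in = np.abs(np.fft.fftn(v.grid))[beyond] ** 2
        p_out = np.abs(np.fft.fftn(out.grid))[beyond] ** 2
        assert p_out.sum() <= 0.01 * p_in.sum()

    def test_ring_peak_radius_survives_15A_filtering(self):
        spec = MotorPhantomSpec(
            [TubeComponent(radius=40.0, z_center=0.0, height=40.0)],
            box_size=64, voxel_size=2.0,
        )
        v = make_motor_phantom(spec)
        r0 = estimate_feature_radius(radial_profile(v, (-16, 16)), (20, 60))
        r1 = estimate_feature_radius(
            radial_profile(lowpass(v, 15.0), (-16, 16)), (20, 60)
        )
        assert abs(r0 - r1) <= 2.0

    def test_rejects_resolution_at_or_beyond_nyquist(self, c17_phantom):
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass(c17_phantom, 4.0)


def brute_force_fsc(a, b):
    """Independent per-shell correlation by explicit masked summation."""
    n = a.n
    fa, fb = np.fft.fftn(a.grid), np.fft.fftn(b.grid)
    ki = np.fft.fftfreq(n) * n
    rad = np.sqrt(
        ki[:, None, None] ** 2 + ki[None, :, None] ** 2 + ki[None, None, :] ** 2
    )
    out = []
    for s in range(n // 2 + 1):
        mask = np.abs(rad - s) <= 0.5
        num = np.sum((fa[mask] * np.conj(fb[mask])).real)
        den = np.sqrt(np.sum(np.abs(fa[mask]) ** 2) * np.sum(np.abs(fb[mask]) ** 2))
        out.append(num / den if den > 0 else 0.0)
    return np.array(out)


class TestFSC:
    def test_self_correlation_is_one(self, c17_phantom):
        curve = fsc(c17_phantom, c17_phantom)
        np.testing.assert_allclose(curve.correlation, 1.0, atol=1e-12)

    def test_negated_map_gives_minus_one(self, c17_phantom):
        neg = Volume(-c17_phantom.grid, c17_phantom.voxel_size)
        curve = fsc(c17_phantom, neg)
        np.testing.assert_allclose(curve.correlation, -1.0, atol=1e-12)

    def test_symmetric_and_scale_invariant(self, c17_phantom, rng):
        noisy = Volume(
            c17_phantom.grid + rng.normal(0, 0.1, c17_phantom.grid.shape), 2.0
        )
        ab = fsc(c17_phantom, noisy).correlation
        ba = fsc(noisy, c17_phantom).correlation
        np.testing.assert_allclose(ab, ba, atol=1e-12)
        scaled = Volume(7.5 * noisy.grid, 2.0)
        np.testing.assert_allclose(
            fsc(c17_phantom, scaled).correlation, ab, atol=1e-9
        )

    def test_mismatched_grids_rejected(self, c17_phantom):
        other = Volume(np.zeros((32, 32, 32)), 2.0)
        with pytest.raises(ValueError):
            fsc(c17_phantom, other)

    def test_resolution_against_brute_force_shells(self, c17_phantom, rng):
        noisy = Volume(
            c17_phantom.grid + rng.normal(0, 0.5, c17_phantom.grid.shape), 2.0
        )
        blurred = lowpass(noisy, 10.0)
        curve = fsc(c17_phantom, blurred)
        np.testing.assert_allclose(
            curve.correlation, brute_force_fsc(c17_phantom, blurred), atol=1e-9
        )
        res = resolution_at(curve, FSC_MAP_MODEL)
        # brute-force crossing from the independent shell correlation
        bf = brute_force_fsc(c17_phantom, blurred)
        idx = np.where(bf < FSC_MAP_MODEL)[0]
        first = idx[idx > 0][0]
        dk = curve.shell_width
        assert res is not None
        assert 1.0 / (first + 1) / dk <= res <= 1.0 / max(first - 1, 1) / dk

    def test_never_crossing_reports_beyond_nyquist(self, c17_phantom):
        assert resolution_at(fsc(c17_phantom, c17_phantom), 0.5) is None
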