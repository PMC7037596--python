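"""Peak fitting, d-spacing extraction and orientation analysis."""

import numpy as np
import pytest

from conftest import single_region_phantom
from valvescan.geometry import q_of_d
from valvescan.peaks import (
    PeakError,
    ReflectionAbsent,
    collagen_d_period,
    fit_peak,
    muscle_d11,
    orientation,
)
from valvescan.reduction import RadialProfile, sector_profile, subtract_background
from valvescan.render import render_diffraction


def gaussian_profile(amp=100.0, center=0.0469, sigma=0.001, baseline=0.0,
                     span=(0.04, 0.054), n=200):
    q = np.linspace(*span, n)
    y = amp * np.exp(-0.5 * ((q - center) / sigma) ** 2) + baseline
    return RadialProfile(q=q, intensity=y, sector="meridional", half_angle=15.0)


def meridional(frame):
    return subtract_background(sector_profile(frame, "meridional"))


def equatorial(frame):
    return subtract_background(sector_profile(frame, "equatorial"))


class TestFitPeak:
    def test_noise_free_self_fit_is_exact(self):
        prof = gaussian_profile()
        fit = fit_peak(prof, (0.042, 0.052))
        assert fit.ok
        assert fit.center_q == pytest.approx(0.0469, rel=1e-6)
        assert fit.sigma_q == pytest.approx(0.001, rel=1e-6)
        assert fit.area == pytest.approx(100.0 * 0.001 * np.sqrt(2 * np.pi), rel=1e-6)

    def test_refit_of_own_model_is_idempotent(self):
        fit1 = fit_peak(gaussian_profile(baseline=5.0), (0.042, 0.052))
        q = np.linspace(0.042, 0.052, 150)
        model = (fit1.params["amp"] * np.exp(-0.5 * ((q - fit1.center_q) / fit1.sigma_q) ** 2)
                 + (fit1.baseline - fit1.params["b1"] * fit1.center_q) + fit1.params["b1"] * q)
        prof2 = RadialProfile(q=q, intensity=model, sector="meridional", half_angle=15.0)
        fit2 = fit_peak(prof2, (0.042, 0.052))
        assert fit2.center_q == pytest.approx(fit1.center_q, abs=1e-9)
        assert fit2.sigma_q == pytest.approx(fit1.sigma_q, abs=1e-9)

    def test_flat_profile_returns_flagged_null(self):
        q = np.linspace(0.04, 0.05, 50)
        prof = RadialProfile(q=q, intensity=np.full(50, 3.0), sector="full",
                             half_angle=15.0)
        fit = fit_peak(prof, (0.04, 0.05))
        assert not fit.ok
        assert np.isnan(fit.area)

    def test_too_few_points_rejected(self):
        prof = gaussian_profile(n=30)
        with pytest.raises(PeakError):
            fit_peak(prof, (0.0468, 0.047))

    def test_pseudo_voigt_model(self):
        prof = gaussian_profile()
        fit = fit_peak(prof, (0.042, 0.052), model="pseudo_voigt")
        assert fit.ok
        assert fit.center_q == pytest.approx(0.0469, rel=1e-4)

    @pytest.mark.parametrize("seed", range(12))
    def test_noisy_center_recovery(self, seed):
        """Poisson noise at decent SNR leaves the center within 0.2 sigma."""
        rng = np.random.default_rng(seed)
        prof = gaussian_profile(amp=400.0, baseline=20.0)
        noisy = RadialProfile(q=prof.q, intensity=rng.poisson(prof.intensity).astype(float),
                              sector="meridional", half_angle=15.0)
        fit = fit_peak(noisy, (0.042, 0.052))
        assert abs(fit.center_q - 0.0469) < 0.2 * 0.001


class TestCollagenD:
    def test_fifth_order_arithmetic(self):
        """center q = 2*pi/134 A^-1 means d5 = 13.40 nm and D = 67.0 nm."""
        prof = gaussian_profile(center=q_of_d(134.0))
        D, fit = collagen_d_period(prof)
        assert fit.d_angstrom / 10.0 == pytest.approx(13.40, abs=5e-4)
        assert D == pytest.approx(67.0, rel=2e-4)

    def test_rendered_d_period_recovered(self, geometry):
        ph = single_region_phantom(d_period_nm=67.67)
        frame = render_diffraction(ph, 5.0, 0.0, geometry)
        D, _ = collagen_d_period(meridional(frame), d0_guess_nm=67.67)
        assert D == pytest.approx(67.67, rel=0.002)

    def test_collagen_free_frame_raises(self, geometry):
        ph = single_region_phantom(muscle_fraction=1.0)
        frame = render_diffraction(ph, 5.0, 0.0, geometry)
        with pytest.raises(ReflectionAbsent):
            collagen_d_period(meridional(frame))

    def test_order_consistency(self, geometry):
        """All visible orders report the same D within 0.3%."""
        ph = single_region_phantom(muscle_fraction=0.0)
        frame = render_diffraction(ph, 5.0, 0.0, geometry)
        prof = meridional(frame)
        ds = []
        for n in (3, 5, 7, 9):
            D, _ = collagen_d_period(prof, d0_guess_nm=67.0, order=n)
            ds.append(D)
        assert np.ptp(ds) / np.mean(ds) < 0.003


class TestMuscleD11:
    def test_absent_in_muscle_free_frame(self, geometry):
        ph = single_region_phantom(muscle_fraction=0.0)
        frame = render_diffraction(ph, 5.0, 0.0, geometry)
        with pytest.raises(ReflectionAbsent):
            muscle_d11(equatorial(frame))

    def test_rendered_d11_recovered(self, geometry):
        ph = single_region_phantom(muscle_fraction=0.8)
        frame = render_diffraction(ph, 5.0, 0.0, geometry)
        d11, fit = muscle_d11(equatorial(frame))
        assert d11 == pytest.approx(21.5, rel=0.005)
        assert fit.params.get("relative_measure") is True

    def test_series_shrinks_with_strain(self, geometry):
        """The (1,1) spacing decreases monotonically across strain levels."""
        ph = single_region_phantom(muscle_fraction=0.8).with_overrides(
            d11_strain_gain=0.3)
        vals = []
        for eps in (0.0, 0.02, 0.04, 0.06, 0.08, 0.10):
            frame = render_diffraction(ph, 5.0, eps, geometry)
            vals.append(muscle_d11(equatorial(frame))[0])
        assert np.all(np.diff(vals) < 0)


class TestOrientation:
    @pytest.mark.parametrize("sigma", [5.0, 10.0, 20.0, 30.0])
    def test_angle_and_spread_recovered(self, geometry, sigma):
        ph = single_region_phantom(sigma_chi=sigma, muscle_fraction=0.0)
        frame = render_diffraction(ph, 5.0, 0.0, geometry)
        res = orientation(frame, (q_of_d(134.0) * 0.96, q_of_d(134.0) * 1.04))
        assert not res.isotropic
        assert abs(res.angle - 90.0) <= 2.0
        assert abs(res.spread - sigma) <= 2.0

    def test_isotropic_ring_yields_dot(self, geometry):
        frame = render_diffraction(single_region_phantom(muscle_fraction=0.0),
                                   5.0, 0.0, geometry, isotropic=True)
        res = orientation(frame, (q_of_d(134.0) * 0.96, q_of_d(134.0) * 1.04))
        assert res.isotropic
        a, b, _ = res.ellipse
        assert b == pytest.approx(0.12 * a)

    def test_minor_axis_inverse_to_spread(self, geometry):
        """b is inversely proportional to the angular spread: a 4x spread
        ratio gives a 4x minor-axis ratio, and b*spread is constant."""
        results = {}
        for sigma in (10.0, 40.0):
            ph = single_region_phantom(sigma_chi=sigma, muscle_fraction=0.0)
            frame = render_diffraction(ph, 5.0, 0.0, geometry)
            results[sigma] = orientation(
                frame, (q_of_d(134.0) * 0.96, q_of_d(134.0) * 1.04))
        b10, b40 = results[10.0].ellipse[1], results[40.0].ellipse[1]
        s10, s40 = results[10.0].spread, results[40.0].spread
        assert b10 * s10 == pytest.approx(b40 * s40, rel=1e-9)   # b = kappa/spread
        assert b10 / b40 == pytest.approx(s40 / s10, rel=1e-9)

    def test_rotation_equivariance(self, geometry):
        """Rotating the pattern by delta rotates the reported angle by delta."""
        band = (q_of_d(134.0) * 0.96, q_of_d(134.0) * 1.04)
        ph = single_region_phantom(sigma_chi=10.0, muscle_fraction=0.0)
        base = orientation(render_diffraction(ph, 5.0, 0.0, geometry), band)
        for delta in (20.0, 45.0, 120.0):
            frame = render_diffraction(ph, 5.0, 0.0, geometry,
                                       fiber_axis_deg=90.0 + delta)
            res = orientation(frame, band)
            diff = (res.angle - base.angle - delta + 90.0) % 180.0 - 90.0
            assert abs(diff) <= 1.0

    def test_ellipse_invariant(self):
        from valvescan.peaks import OrientationResult, PeakError
        with pytest.raises(PeakError):
            OrientationResult(10.0, 2.0, False, (1.0, 1.5, 10.0))
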