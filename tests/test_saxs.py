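"""Debye forward model, Guinier, p(r), IFT, Porod, mass, frame reduction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from archkit.core import ScatteringCurve
from archkit.saxs import (coordinate_rg, debye_curve, fit_curve, guinier,
                          mm_from_I0, pofr_from_structure, pofr_ift,
                          porod_volume, reduce)
from archkit.synth import simulate_curve

from conftest import sphere_form_factor, sphere_grid_fill

R_NM = 3.0  # sphere radius in nm (points are stored in Angstrom)


class TestDebye:
    def test_single_point_flat(self):
        s = np.linspace(0.0, 5.0, 20)
        c = debye_curve(np.zeros((1, 3)), s)
        np.testing.assert_allclose(c.I, 1.0)

    def test_two_point_closed_form(self):
        d_nm = 1.9
        s = np.linspace(0.0, 5.0, 50)
        c = debye_curve(np.array([[0.0, 0, 0], [d_nm * 10, 0, 0]]), s)
        expected = 2.0 * (1.0 + np.sinc(s * d_nm / np.pi))
        np.testing.assert_allclose(c.I, expected, rtol=1e-12)

    def test_zero_angle_equals_total_squared(self, sphere_points):
        c = debye_curve(sphere_points[:500], np.array([0.0]))
        assert c.I[0] == pytest.approx(500.0 ** 2)

    def test_histogram_matches_direct(self, sphere_points):
        s = np.linspace(0.05, 2.0, 30)
        direct = debye_curve(sphere_points[:400], s, direct=True)
        binned = debye_curve(sphere_points[:400], s, direct=False)
        np.testing.assert_allclose(binned.I, direct.I, rtol=1e-3)

    def test_rigid_transform_invariant(self, sphere_points):
        pts = sphere_points[:300]
        s = np.linspace(0.05, 2.0, 20)
        R = Rotation.from_euler("xyz", [20, 50, 110], degrees=True).as_matrix()
        a = debye_curve(pts, s)
        b = debye_curve(pts @ R.T + np.array([30.0, -5, 12]), s)
        np.testing.assert_allclose(a.I, b.I, rtol=1e-9)

    def test_sphere_form_factor(self):
        # deterministic ~5000-point fill; the self-scattering constant N is
        # subtracted for the continuum comparison, and the relative check
        # excludes the neighbourhood of the form-factor zero (where relative
        # error is ill-defined for any discrete sample)
        pts = sphere_grid_fill()
        n = len(pts)
        s = np.linspace(0.05, 6.0 / R_NM, 60)
        c = debye_curve(pts, s)
        est = (c.I - n) / (n * (n - 1))
        ff = sphere_form_factor(s * R_NM)
        body = ff > 0.01 * ff.max()
        assert np.abs(est[body] / ff[body] - 1).max() < 0.02


class TestFitCurve:
    def test_exact_scale(self):
        s = np.linspace(0.05, 3, 40)
        I = np.exp(-s ** 2)
        res = fit_curve(ScatteringCurve(s, 2 * I), ScatteringCurve(s, I))
        assert res.scale == pytest.approx(2.0)
        assert res.chi == pytest.approx(0.0, abs=1e-12)

    def test_chi_near_one_for_consistent_noise(self):
        rng = np.random.default_rng(0)
        s = np.linspace(0.02, 3, 500)
        I = 1e5 * np.exp(-(s * 2.0) ** 2 / 3)
        sigma = 0.02 * I
        noisy = ScatteringCurve(s, I + rng.normal(size=500) * sigma, sigma)
        res = fit_curve(noisy, ScatteringCurve(s, I))
        assert res.chi == pytest.approx(1.0, rel=0.10)

    def test_mismatched_model_fits_worse(self, sphere_points):
        s = np.linspace(0.05, 2.0, 80)
        sphere = debye_curve(sphere_points[:800], s)
        dumbbell_pts = np.vstack([sphere_points[:400] * 0.5,
                                  sphere_points[:400] * 0.5 + [45.0, 0, 0]])
        dumbbell = debye_curve(dumbbell_pts, s)
        data = ScatteringCurve(s, sphere.I, 0.01 * sphere.I)
        good = fit_curve(data, sphere).chi
        bad = fit_curve(data, dumbbell).chi
        assert bad > good

    def test_degenerate_inputs(self):
        s = np.array([0.1, 0.2])
        with pytest.raises(ValueError):
            fit_curve(ScatteringCurve(s[:1], [1.0]), ScatteringCurve(s[:1], [1.0]))
        with pytest.raises(ValueError):
            fit_curve(ScatteringCurve(s, [1, 1]), ScatteringCurve(s, [0, 0]))


class TestGuinier:
    def test_exact_guinier_curve(self):
        rg, i0 = 2.0, 100.0
        s = np.linspace(0.01, 1.0, 200)
        c = ScatteringCurve(s, i0 * np.exp(-(s * rg) ** 2 / 3))
        fit = guinier(c)
        assert fit.Rg == pytest.approx(rg, abs=1e-6)
        assert fit.I0 == pytest.approx(i0, rel=1e-6)
        assert fit.s_range_used[1] * fit.Rg <= 1.3 + 1e-9

    def test_sphere_closed_form(self):
        s = np.linspace(0.005, 4.0, 1000)
        c = ScatteringCurve(s, sphere_form_factor(s * R_NM))
        fit = guinier(c)
        assert fit.Rg == pytest.approx(np.sqrt(3.0 / 5.0) * R_NM, rel=0.01)

    def test_noisy_simulated_dumbbell_matches_coordinates(self, sphere_points):
        pts = np.vstack([sphere_points[:1500] * 0.5,
                         sphere_points[:1500] * 0.5 + [45.0, 0, 0]])
        curve = simulate_curve(pts, np.linspace(0.02, 1.5, 80),
                               rel_noise=0.01, seed=4)
        fit = guinier(curve)
        assert fit.Rg == pytest.approx(coordinate_rg(pts), rel=0.03)

    def test_rising_curve_rejected(self):
        s = np.linspace(0.01, 1, 50)
        with pytest.raises(ValueError):
            guinier(ScatteringCurve(s, np.exp(+s ** 2)))


class TestCoordinateRg:
    def test_two_points(self):
        assert coordinate_rg(np.array([[0.0, 0, 0], [20.0, 0, 0]])) == pytest.approx(1.0)

    def test_sphere_sample(self, sphere_points):
        assert coordinate_rg(sphere_points) == pytest.approx(
            np.sqrt(3.0 / 5.0) * R_NM, rel=0.01)

    def test_rigid_invariance(self, sphere_points):
        pts = sphere_points[:200]
        R = Rotation.from_euler("zyx", [11, 22, 33], degrees=True).as_matrix()
        assert coordinate_rg(pts @ R.T + 100.0) == pytest.approx(
            coordinate_rg(pts), abs=1e-12)


class TestPofrHistogram:
    def test_two_points_single_bin(self):
        d = pofr_from_structure(np.array([[0.0, 0, 0], [38.0, 0, 0]]))
        occupied = d.r[d.p > 0]
        assert len(occupied) == 1
        assert occupied[0] == pytest.approx(3.8, abs=0.05)
        assert d.dmax == pytest.approx(3.8)

    def test_sphere_pair_distance_closed_form(self, sphere_points):
        d = pofr_from_structure(sphere_points, bin_width=0.05)
        r = d.r
        x = r / R_NM
        exact = np.where(x <= 2.0,
                         3 * r ** 2 / R_NM ** 3
                         * (1 - 0.75 * x + 0.0625 * x ** 3) / 4.0, 0.0)
        exact /= np.trapezoid(exact, r)
        err = np.sqrt(np.trapezoid((d.p - exact) ** 2, r)
                      / np.trapezoid(exact ** 2, r))
        assert err < 0.03


class TestIft:
    def _two_gaussian(self):
        dmax = 8.0
        r = np.linspace(0, dmax, 201)
        p = (0.6 * np.exp(-((r - 1.7) / 0.7) ** 2)
             + 0.9 * np.exp(-((r - 3.8) / 1.1) ** 2))
        p[0] = p[-1] = 0.0
        return r, p, dmax

    def test_recovers_known_pofr(self):
        rng = np.random.default_rng(2)
        r, p, dmax = self._two_gaussian()
        s = np.linspace(0.05, 4.0, 120)
        K = 4 * np.pi * np.sinc(np.outer(s, r) / np.pi) * (r[1] - r[0])
        I = K @ p
        sigma = 0.01 * (np.abs(I) + 0.005 * I.max())
        res = pofr_ift(ScatteringCurve(s, I + rng.normal(size=s.size) * sigma,
                                       sigma), dmax=dmax)
        norm = np.trapezoid(p, r)
        rg_true = np.sqrt(np.trapezoid(p * r ** 2, r) / (2 * norm))
        pi = np.interp(r, res.dist.r, res.dist.p)
        pn, pin = p / norm, pi / np.trapezoid(pi, r)
        l2 = np.sqrt(np.trapezoid((pin - pn) ** 2, r)
                     / np.trapezoid(pn ** 2, r))
        assert l2 < 0.05
        assert res.rg == pytest.approx(rg_true, rel=0.02)

    def test_sphere_rg(self):
        s = np.linspace(0.02, 4.0, 200)
        I = sphere_form_factor(s * R_NM)
        res = pofr_ift(ScatteringCurve(s, I, 0.01 * I + 1e-8), dmax=2 * R_NM)
        assert res.rg == pytest.approx(np.sqrt(3 / 5) * R_NM, rel=0.02)

    def test_too_small_dmax_warns(self):
        rng = np.random.default_rng(3)
        r, p, dmax = self._two_gaussian()
        s = np.linspace(0.05, 4.0, 120)
        K = 4 * np.pi * np.sinc(np.outer(s, r) / np.pi) * (r[1] - r[0])
        I = K @ p
        sigma = 0.01 * (np.abs(I) + 0.005 * I.max())
        curve = ScatteringCurve(s, I + rng.normal(size=s.size) * sigma, sigma)
        with pytest.warns(UserWarning, match="dmax"):
            pofr_ift(curve, dmax=dmax / 2)


class TestPorod:
    def test_sphere_closed_form(self):
        s = np.linspace(0.02, 10.0, 1000)
        I = sphere_form_factor(s * R_NM)
        vp = porod_volume(ScatteringCurve(s, I), I0=1.0)
        assert vp == pytest.approx(4 / 3 * np.pi * R_NM ** 3, rel=0.10)

    def test_scale_invariant(self):
        s = np.linspace(0.02, 10.0, 500)
        I = sphere_form_factor(s * R_NM)
        a = porod_volume(ScatteringCurve(s, I), I0=1.0)
        b = porod_volume(ScatteringCurve(s, 7.5 * I), I0=7.5)
        assert a == pytest.approx(b, rel=1e-9)

    def test_dumbbell_envelope_volume(self):
        # two spheres of radius 1.5 nm, centres 4.5 nm apart (analytic curve)
        R, d = 1.5, 4.5
        s = np.linspace(0.02, 10.0, 1000)
        x = s * R
        amp = 3 * (np.sin(x) - x * np.cos(x)) / x ** 3
        I = 2 * amp ** 2 * (1 + np.sinc(s * d / np.pi))
        vp = porod_volume(ScatteringCurve(s, I), I0=4.0)
        assert vp == pytest.approx(2 * 4 / 3 * np.pi * R ** 3, rel=0.15)


class TestMassEstimate:
    def test_identity_and_linearity(self):
        assert mm_from_I0(10.0, 1.0, 10.0, 1.0) == pytest.approx(66.0)
        assert mm_from_I0(5.0, 1.0, 10.0, 1.0) == pytest.approx(33.0)

    def test_round_trip(self):
        target = 20.6
        i0 = target / 66.0 * (123.0 / 4.5) * 2.0  # sample at 2 mg/mL
        assert mm_from_I0(i0, 2.0, 123.0, 4.5) == pytest.approx(target)

    def test_scale_invariant_in_detector_units(self):
        a = mm_from_I0(5.0, 1.0, 10.0, 1.0)
        b = mm_from_I0(5000.0, 1.0, 10000.0, 1.0)
        assert a == pytest.approx(b)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mm_from_I0(1.0, 0.0, 1.0, 1.0)


class TestReduce:
    def _frame(self, s, I, sigma=None):
        return ScatteringCurve(s, I, sigma)

    def test_identity(self):
        s = np.linspace(0.05, 3, 50)
        I = np.exp(-s ** 2)
        curve, report = reduce([self._frame(s, I)] * 4, None, 1.0)
        np.testing.assert_allclose(curve.I, I)
        assert report["n_rejected"] == 0

    def test_outlier_frame_dropped(self):
        s = np.linspace(0.05, 3, 50)
        I = np.exp(-s ** 2)
        frames = [self._frame(s, I)] * 7 + [self._frame(s, 10 * I)]
        curve, report = reduce(frames, None, 1.0)
        assert report["n_rejected"] == 1
        assert report["rejected_indices"] == [7]
        np.testing.assert_allclose(curve.I, I)

    def test_forward_construction_recovered(self):
        s = np.linspace(0.05, 3, 60)
        excess = 5.0 * np.exp(-s ** 2)
        buffer_I = 0.8 + 0.1 * s
        conc = 2.5
        frames = [self._frame(s, conc * excess + buffer_I) for _ in range(6)]
        curve, _ = reduce(frames, self._frame(s, buffer_I), conc)
        np.testing.assert_allclose(curve.I, excess, rtol=1e-12)

    def test_all_rejected_error(self):
        s = np.linspace(0.05, 3, 10)
        with pytest.raises(ValueError):
            reduce([], None, 1.0)
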