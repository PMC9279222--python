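"""Debye forward model and SAS curve statistics."""

import numpy as np
import pytest

from beltsas import (
    SASCurve,
    ScatteringBody,
    coarsen_body,
    debye_intensity,
    distance_distribution,
    guinier_rg,
    load_curve,
    porod_volume,
    reduced_chi2,
)
from conftest import sobol_ball, sphere_form_factor, uniform_ball


class TestDebye:
    def test_single_center_is_flat(self):
        c = debye_intensity(ScatteringBody(np.zeros((1, 3)), [2.0]),
                            np.linspace(0.01, 1, 20))
        np.testing.assert_allclose(c.intensity, 4.0)

    def test_two_centers_closed_form(self):
        r = 10.0
        q = np.linspace(0.01, 1, 50)
        body = ScatteringBody(np.array([[0.0, 0, 0], [r, 0, 0]]), [1.0, 1.0])
        c = debye_intensity(body, q, method="exact")
        expected = 2 + 2 * np.sin(q * r) / (q * r)
        np.testing.assert_allclose(c.intensity, expected, rtol=1e-12)

    def test_i0_equals_total_b_squared(self):
        rng = np.random.default_rng(3)
        body = ScatteringBody(rng.random((50, 3)) * 10, rng.random(50))
        c = debye_intensity(body, np.array([1e-6]), method="exact")
        assert c.intensity[0] == pytest.approx(body.total_b**2, rel=1e-8)

    def test_sphere_cloud_matches_analytic_form_factor(self):
        """Uniform points in a ball reproduce the homogeneous-sphere
        form factor; relative comparison is made away from the form
        factor's zero (qa ~ 4.49) where it is ill-conditioned."""
        a = 20.0
        n = 8192
        body = ScatteringBody(sobol_ball(n, a), np.ones(n))
        q = np.linspace(0.02, 5.0 / a, 50)
        c = debye_intensity(body, q, method="histogram", bin_width=0.2)
        qa = q * a
        expected = n**2 * sphere_form_factor(qa)
        mask = np.abs(qa - 4.493) > 0.3
        np.testing.assert_allclose(
            c.intensity[mask], expected[mask], rtol=0.02)

    def test_histogram_agrees_with_exact(self):
        rng = np.random.default_rng(9)
        body = ScatteringBody(rng.random((400, 3)) * 30,
                              rng.standard_normal(400))
        q = np.linspace(0.01, 0.4, 30)
        exact = debye_intensity(body, q, method="exact").intensity
        hist = debye_intensity(body, q, method="histogram",
                               bin_width=0.05).intensity
        np.testing.assert_allclose(hist, exact, rtol=5e-3,
                                   atol=1e-4 * np.abs(exact).max())

    def test_nonnegative_for_real_b(self):
        rng = np.random.default_rng(4)
        body = ScatteringBody(rng.random((200, 3)) * 40,
                              rng.standard_normal(200))
        c = debye_intensity(body, np.linspace(0.01, 0.5, 40), method="exact")
        assert np.all(c.intensity >= -1e-9 * np.abs(c.intensity).max())


class TestReducedChi2:
    def _curve(self, y, sigma=1.0):
        q = np.linspace(0.01, 0.5, len(y))
        return SASCurve(q, np.asarray(y, float),
                        np.full(len(y), float(sigma)))

    def test_identical_curves_give_zero(self):
        data = self._curve(np.linspace(10, 1, 50))
        assert reduced_chi2(data, data)[0] == pytest.approx(0.0, abs=1e-20)

    def test_one_sigma_offset_gives_one(self):
        y = np.linspace(10, 1, 2000)
        data = self._curve(y)
        model = self._curve(y + 1.0)
        chi2, _, _ = reduced_chi2(model, data, fit_scale=False)
        assert chi2 == pytest.approx(1.0, rel=1e-3)

    def test_five_point_hand_computation(self):
        q = np.arange(1, 6) * 0.1
        data = SASCurve(q, [4.0, 3.0, 2.0, 1.5, 1.0],
                        [0.5, 0.4, 0.2, 0.3, 0.1])
        model = SASCurve(q, [4.2, 2.9, 2.2, 1.4, 1.05])
        expected = np.sum(
            ((np.array([4.2, 2.9, 2.2, 1.4, 1.05])
              - np.array([4.0, 3.0, 2.0, 1.5, 1.0]))
             / np.array([0.5, 0.4, 0.2, 0.3, 0.1])) ** 2) / 5
        chi2, scale, _ = reduced_chi2(model, data, fit_scale=False)
        assert chi2 == pytest.approx(expected, rel=1e-12)

    def test_low_q_cut_removes_aggregation_upturn(self):
        q = np.linspace(0.005, 0.3, 120)
        clean = np.exp(-(q**2) * 900 / 3)
        upturn = clean * (1 + 5 * np.exp(-(q / 0.01) ** 2))
        data = SASCurve(q, upturn, 0.01 * clean)
        model = SASCurve(q, clean)
        full = reduced_chi2(model, data, fit_scale=True)[0]
        cut = reduced_chi2(model, data, fit_scale=True, q_min=0.02)[0]
        assert cut < full

    def test_too_few_points_rejected(self):
        data = self._curve([1.0, 2.0])
        with pytest.raises(ValueError, match="fewer points"):
            reduced_chi2(data, data, n_free=5)

    def test_fitted_scale_recovers_factor(self):
        y = np.linspace(10, 1, 50)
        data = self._curve(3.7 * y, sigma=0.01)
        model = self._curve(y)
        _, scale, _ = reduced_chi2(model, data)
        assert scale == pytest.approx(3.7, rel=1e-6)


class TestGuinier:
    def test_exact_gaussian_curve(self):
        rg = 30.0
        q = np.linspace(0.001, 0.06, 100)
        curve = SASCurve(q, 5.0 * np.exp(-(q**2) * rg**2 / 3))
        est, i0 = guinier_rg(curve)
        assert est == pytest.approx(rg, rel=0.005)
        assert i0 == pytest.approx(5.0, rel=0.01)

    def test_sphere_cloud_rg(self):
        a = 25.0
        pts = uniform_ball(6000, a, seed=2)
        body = ScatteringBody(pts, np.ones(len(pts)))
        q = np.geomspace(0.002, 0.08, 80)
        curve = debye_intensity(body, q, method="histogram", bin_width=0.3)
        est, _ = guinier_rg(curve)
        assert est == pytest.approx(a * np.sqrt(3 / 5), rel=0.02)

    def test_rg_matches_second_moment_of_body(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((3000, 3)) * 12
        body = ScatteringBody(pts, np.ones(3000))
        com = pts.mean(axis=0)
        rg_direct = np.sqrt(np.mean(np.sum((pts - com) ** 2, axis=1)))
        q = np.geomspace(0.002, 0.1, 80)
        curve = debye_intensity(body, q, method="histogram", bin_width=0.3)
        est, _ = guinier_rg(curve)
        assert est == pytest.approx(rg_direct, rel=0.01)

    def test_increasing_curve_rejected(self):
        q = np.linspace(0.01, 0.1, 30)
        with pytest.raises(ValueError, match="Guinier"):
            guinier_rg(SASCurve(q, np.linspace(1, 5, 30)))


class TestPorod:
    def test_sphere_volume_within_ten_percent(self):
        a = 20.0
        q = np.geomspace(0.005, 12.0 / a, 400)
        expected_curve = sphere_form_factor(q * a)
        curve = SASCurve(q, expected_curve)
        vp = porod_volume(curve, background="none")
        assert vp == pytest.approx(4 / 3 * np.pi * a**3, rel=0.10)

    def test_scale_invariance(self):
        a = 20.0
        q = np.geomspace(0.005, 0.6, 300)
        y = sphere_form_factor(q * a)
        v1 = porod_volume(SASCurve(q, y))
        v2 = porod_volume(SASCurve(q, 137.0 * y))
        assert v2 == pytest.approx(v1, rel=1e-9)

    def test_all_zero_curve_rejected(self):
        q = np.linspace(0.01, 0.5, 50)
        with pytest.raises(ValueError):
            porod_volume(SASCurve(q, np.zeros(50)))


class TestDistanceDistribution:
    def test_two_points(self):
        body = ScatteringBody(np.array([[0.0, 0, 0], [10.0, 0, 0]]), [1.0, 1.0])
        r, p, dmax = distance_distribution(body, n_bins=20)
        assert dmax == pytest.approx(10.0)
        assert p[-1] > 0 and np.sum(p > 0) == 1

    def test_sphere_p_of_r_peak_position(self):
        a = 15.0
        pts = uniform_ball(4000, a, seed=6)
        body = ScatteringBody(pts, np.ones(len(pts)))
        r, p, dmax = distance_distribution(body, n_bins=60)
        assert dmax == pytest.approx(2 * a, rel=0.05)
        # analytic p(r) of a sphere peaks near 1.05 a
        assert r[np.argmax(p)] == pytest.approx(1.05 * a, rel=0.10)

    def test_dmax_rotation_invariant(self):
        rng = np.random.default_rng(7)
        pts = rng.random((100, 3)) * 20
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        b = np.ones(100)
        d1 = distance_distribution(ScatteringBody(pts, b))[2]
        d2 = distance_distribution(ScatteringBody(pts @ rot.T, b))[2]
        assert d2 == pytest.approx(d1, rel=1e-9)


class TestCoarsen:
    def test_preserves_total_b(self):
        rng = np.random.default_rng(5)
        body = ScatteringBody(rng.random((5000, 3)) * 50,
                              rng.standard_normal(5000))
        coarse = coarsen_body(body, 4.0)
        assert coarse.total_b == pytest.approx(body.total_b, abs=1e-9)
        assert len(coarse.b) < len(body.b)

    def test_intensity_preserved_at_low_q(self):
        rng = np.random.default_rng(6)
        body = ScatteringBody(rng.random((8000, 3)) * 60, np.ones(8000))
        q = np.linspace(0.01, 0.5, 40)
        full = debye_intensity(body, q, method="histogram").intensity
        coarse = debye_intensity(coarsen_body(body, 1.5), q,
                                 method="histogram").intensity
        np.testing.assert_allclose(coarse, full, rtol=0.01)


class TestCurveIO:
    def test_roundtrip(self, tmp_path):
        q = np.linspace(0.01, 0.5, 30)
        curve = SASCurve(q, np.exp(-q), 0.01 * np.exp(-q))
        path = tmp_path / "c.dat"
        curve.save(path)
        back = load_curve(path)
        np.testing.assert_allclose(back.q, q)
        np.testing.assert_allclose(back.sigma, curve.sigma)

    def test_nm_autodetected(self, tmp_path):
        q_nm = np.linspace(0.1, 5.0, 30)  # max > 2 -> nm^-1
        path = tmp_path / "nm.dat"
        np.savetxt(path, np.column_stack([q_nm, np.ones(30)]))
        curve = load_curve(path)
        np.testing.assert_allclose(curve.q, q_nm / 10.0)

    def test_comment_lines_ignored(self, tmp_path):
        path = tmp_path / "h.dat"
        path.write_text("# header\n0.01 5.0 0.1\n0.02 4.0 0.1\n")
        curve = load_curve(path)
        assert len(curve.q) == 2
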