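"""Normal velocity, curvature, areas, collapse and extrapolation."""
import numpy as np
import pytest

from cdrwave import Contour, ContourSeries
from cdrwave.kinematics import (
    KinematicsError,
    curvature_velocity_correlation,
    enclosed_area,
    fit_extrapolate_v0,
    local_curvature,
    local_normal_velocity,
    series_kinematics,
    velocity_area_collapse,
)
from cdrwave.phantoms import PhantomParams, ring_radius
from conftest import circle_contour


def parabola_series(v0=0.2, t_rev=100.0, dt=5.0, t0=20.0):
    """Analytic circle contours following the parabolic radius law."""
    p = PhantomParams(v0=v0, t_rev=t_rev)
    frames, times, contours = [], [], []
    k = 0
    t = t0
    while t <= 2 * t_rev - t0:
        r = float(ring_radius(p, t))
        if r > 1.5:
            frames.append(k)
            times.append(t)
            n = max(24, int(round(2 * np.pi * r / 0.5)))
            contours.append(circle_contour(0.0, 0.0, r, n=n))
        k += 1
        t += dt
    return ContourSeries(frames, times, contours)


class TestNormalVelocity:
    def test_uniform_expansion_is_plus_010(self):
        v = local_normal_velocity(circle_contour(0, 0, 10, 100),
                                  circle_contour(0, 0, 11, 100), dt=10.0)
        assert np.allclose(v, 0.10, atol=1e-3)

    def test_uniform_shrinkage_is_minus_010(self):
        v = local_normal_velocity(circle_contour(0, 0, 11, 100),
                                  circle_contour(0, 0, 10, 100), dt=10.0)
        assert np.allclose(v, -0.10, atol=1e-3)

    def test_pure_translation_projects_on_cosine(self):
        d, dt = 0.6, 10.0
        c0 = circle_contour(0, 0, 10, 180)
        c1 = circle_contour(d, 0, 10, 180)
        v = local_normal_velocity(c0, c1, dt)
        ang = np.arctan2(c0.y, c0.x)
        # closed form: ray-circle intersection along the outward normal
        expected = (np.sqrt(100 - (d * np.sin(ang)) ** 2)
                    - 10 + d * np.cos(ang)) / dt
        assert np.nanmax(np.abs(v - expected)) < 0.02 * d / dt

    def test_unrelated_contours_raise(self):
        with pytest.raises(KinematicsError):
            local_normal_velocity(circle_contour(0, 0, 2, 30),
                                  circle_contour(100, 100, 2, 30), 1.0)


class TestCurvature:
    def test_circle_curvature_is_inverse_radius(self):
        for r in [5.0, 10.0, 20.0]:
            c = circle_contour(0, 0, r, int(2 * np.pi * r / 0.8))
            kappa = local_curvature(c, window=2.4)
            assert np.allclose(kappa, 1 / r, rtol=0.01)

    def test_straight_edges_have_zero_curvature(self):
        from cdrwave.contours import resample_contour

        rect = resample_contour(
            Contour(np.array([[0, 0], [40, 0], [40, 20], [0, 20]], float)),
            spacing=0.8,
        )
        kappa = local_curvature(rect, window=2.4)
        mid_edge = np.abs(rect.points[:, 1]) < 1e-9
        mid_edge &= (rect.points[:, 0] > 5) & (rect.points[:, 0] < 35)
        assert np.all(np.abs(kappa[mid_edge]) < 1e-6)

    def test_ellipse_vertex_curvature(self):
        a, b = 12.0, 6.0
        t = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        c = Contour(np.column_stack([a * np.cos(t), b * np.sin(t)]))
        kappa = local_curvature(c, window=1.0)
        i = int(np.argmax(c.x))
        assert kappa[i] == pytest.approx(a / b**2, rel=0.02)

    def test_window_below_spacing_raises(self):
        c = circle_contour(0, 0, 10, 60)
        with pytest.raises(KinematicsError):
            local_curvature(c, window=0.1)


class TestArea:
    def test_unit_square(self):
        assert enclosed_area(
            Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float))
        ) == pytest.approx(1.0)

    def test_100gon_approximates_circle(self):
        c = circle_contour(0, 0, 10, 100)
        assert enclosed_area(c) == pytest.approx(np.pi * 100, rel=0.003)

    def test_collinear_polygon_is_zero(self):
        c = Contour(np.array([[0, 0], [1, 0], [2, 0], [3, 0]], float))
        assert enclosed_area(c) == 0.0

    def test_self_intersection_rejected(self):
        bowtie = Contour(np.array([[0, 0], [2, 2], [2, 0], [0, 2]], float))
        with pytest.raises(KinematicsError):
            enclosed_area(bowtie)


class TestSeriesKinematics:
    def test_parabolic_series_velocity_tracks_derivative(self):
        series = parabola_series(v0=0.2, t_rev=100.0, dt=5.0)
        records = series_kinematics(series)
        for r in records[:-1]:
            true = 0.2 * (1 - (r.time_s + 2.5) / 100.0)  # derivative mid-frame
            if abs(true) > 0.02:
                assert r.mean_velocity == pytest.approx(true, rel=0.05)

    def test_normalized_area_is_one_at_maximum(self):
        records = series_kinematics(parabola_series())
        areas = [r.area_um2 for r in records]
        assert records[int(np.argmax(areas))].normalized_area == 1.0

    def test_static_series_zero_velocity(self):
        c = circle_contour(0, 0, 8, 60)
        series = ContourSeries([0, 1, 2], [0.0, 10.0, 20.0],
                               [c, Contour(c.points.copy()),
                                Contour(c.points.copy())])
        records = series_kinematics(series)
        assert all(abs(r.mean_velocity) < 1e-9 for r in records[:-1])

    def test_area_change_matches_perimeter_times_velocity(self):
        # divergence-theorem consistency: dA/dt ≈ P·v̄
        series = parabola_series(v0=0.2, t_rev=100.0, dt=5.0)
        records = series_kinematics(series)
        for i in range(len(records) - 1):
            dadt = (records[i + 1].area_um2 - records[i].area_um2) / 5.0
            perim = 0.5 * (series.contours[i].perimeter()
                           + series.contours[i + 1].perimeter())
            pred = perim * records[i].mean_velocity
            if abs(dadt) > 1.0:
                assert pred == pytest.approx(dadt, rel=0.10)


class TestCollapse:
    def test_single_parabolic_wave_curve_decreases_with_area(self):
        records = series_kinematics(parabola_series())
        curve = velocity_area_collapse([records])
        med = curve.bin_median[np.isfinite(curve.bin_median)]
        assert np.all(np.diff(med) < 1e-12)

    def test_two_identical_waves_give_identical_curve(self):
        records = series_kinematics(parabola_series())
        c1 = velocity_area_collapse([records])
        c2 = velocity_area_collapse([records, records])
        assert np.allclose(c1.bin_median, c2.bin_median, equal_nan=True)

    def test_empty_pool_raises(self):
        records = series_kinematics(parabola_series())
        closing = [r for r in records if r.mean_velocity < 0]
        with pytest.raises(KinematicsError):
            velocity_area_collapse([closing])


class TestExtrapolation:
    @pytest.mark.parametrize("v0", [0.05, 0.13, 0.20, 0.50])
    def test_recovers_generating_v0(self, v0):
        # hold maximal radius at 20 µm so geometry matches observed waves
        t_rev = 40.0 / v0
        records = series_kinematics(
            parabola_series(v0=v0, t_rev=t_rev, dt=t_rev / 60, t0=t_rev / 15))
        fit = fit_extrapolate_v0(velocity_area_collapse([records]))
        assert fit.v0 == pytest.approx(v0, abs=max(0.005, 0.05 * v0))
        assert fit.parabolic

    def test_constant_velocity_flagged_non_parabolic(self):
        # linear R(t): v constant, the quartic collapse cannot hold
        frames, times, contours = [], [], []
        for k, t in enumerate(np.arange(20.0, 200.0, 5.0)):
            contours.append(circle_contour(0, 0, 0.1 * t, 100))
            frames.append(k)
            times.append(t)
        series = ContourSeries(frames, times, contours)
        records = series_kinematics(series)
        # force an artificial maximum so an opening phase exists
        curve = velocity_area_collapse([records])
        fit = fit_extrapolate_v0(curve)
        assert not fit.parabolic

    def test_quartic_fallback_close_to_closed_form(self):
        records = series_kinematics(parabola_series(v0=0.2, dt=2.0))
        curve = velocity_area_collapse([records])
        v_cf = fit_extrapolate_v0(curve, method="closed_form").v0
        v_q = fit_extrapolate_v0(curve, method="quartic").v0
        assert abs(v_cf - v_q) < 0.03


class TestCurvatureVelocityCorrelation:
    def test_expanding_translating_circle_uncorrelated(self):
        # curvature is uniform along each contour; velocity varies with angle
        frames, times, contours = [], [], []
        for k in range(8):
            contours.append(circle_contour(0.3 * k, 0.0, 10 + 0.5 * k, 120))
            frames.append(k)
            times.append(10.0 * k)
        records = series_kinematics(ContourSeries(frames, times, contours))
        r, _ = curvature_velocity_correlation(records)
        assert abs(r) < 0.1

    def test_eikonal_motion_gives_strong_negative_correlation(self):
        # v = v0 − D·κ on a wavy contour: velocity linear in curvature
        ang = np.linspace(0, 2 * np.pi, 240, endpoint=False)
        v0, d_coef, dt = 0.2, 1.0, 2.0
        frames, times, contours = [], [], []
        c = Contour(np.column_stack([
            (10 + 1.5 * np.sin(5 * ang)) * np.cos(ang),
            (10 + 1.5 * np.sin(5 * ang)) * np.sin(ang),
        ]))
        for k in range(4):
            frames.append(k)
            times.append(k * dt)
            contours.append(c)
            kappa = local_curvature(c, window=2.4)
            step = (v0 - d_coef * kappa) * dt
            c = Contour(c.points + step[:, None] * c.normals())
        records = series_kinematics(ContourSeries(frames, times, contours))
        r, _ = curvature_velocity_correlation(records)
        assert r <= -0.9

    def test_uniform_expansion_has_undefined_correlation(self):
        frames = [0, 1, 2]
        times = [0.0, 10.0, 20.0]
        contours = [circle_contour(0, 0, 10 + k, 120) for k in range(3)]
        records = series_kinematics(ContourSeries(frames, times, contours))
        with pytest.raises(KinematicsError):
            curvature_velocity_correlation(records)
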