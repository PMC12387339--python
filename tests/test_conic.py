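"""Conic fitting: interpolation, classification, canonical geometry, shape."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lenscurve as lc
from lenscurve.conic import (
    DegenerateConicError,
    ConicFitError,
    UnsupportedShapeError,
    _eccentricity_invariant,
)

from conftest import ellipse_coefficients, ellipse_points

UNIT_CIRCLE_PTS = [
    (1, 0),
    (-1, 0),
    (0, 1),
    (0, -1),
    (math.sqrt(2) / 2, math.sqrt(2) / 2),
]


class TestInterpolation:
    def test_unit_circle_through_five_points(self):
        c = lc.fit_conic_through_points(UNIT_CIRCLE_PTS)
        expected = np.array([1, 0, 1, 0, 0, -1]) / np.sqrt(3)
        np.testing.assert_allclose(c.as_array(), expected, atol=1e-12)
        x, y = np.array(UNIT_CIRCLE_PTS).T
        assert np.abs(c.evaluate(x, y)).max() <= 1e-9

    def test_axis_aligned_ellipse_axis_ratio(self):
        # x^2/4 + y^2 = 1 sampled at five parameter angles
        pts = ellipse_points(2, 1, 0, 0, 0, np.radians([0, 40, 95, 160, 250]))
        c = lc.fit_conic_through_points(pts)
        assert abs(c.h) < 1e-12 and abs(c.g) < 1e-12 and abs(c.f) < 1e-12
        assert c.a / c.b == pytest.approx(0.25, abs=1e-10)

    def test_five_point_residuals_general_position(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pts = ellipse_points(
                rng.uniform(1, 10),
                rng.uniform(1, 10),
                rng.uniform(-np.pi, np.pi),
                *rng.uniform(-100, 100, 2),
                rng.uniform(0, 2 * np.pi, 5),
            )
            c = lc.fit_conic_through_points(pts)
            assert np.abs(c.evaluate(pts[:, 0], pts[:, 1])).max() <= 1e-9

    def test_total_least_squares_with_noise(self):
        # 20 noisy points on x^2/9 + y^2/4 = 1: TLS conic close to the truth
        rng = np.random.default_rng(11)
        pts = ellipse_points(3, 2, 0, 0, 0, np.linspace(0, 2 * np.pi, 20, endpoint=False))
        pts = pts + rng.normal(0, 0.01, pts.shape)
        c = lc.fit_conic_through_points(pts)
        truth = ellipse_coefficients(3, 2, 0, 0, 0)
        assert np.linalg.norm(c.as_array() - truth.as_array()) <= 1e-2

    @pytest.mark.parametrize(
        "bad",
        [
            [(0, 0), (1, 1), (2, 2), (3, 3)],  # too few
            [(0, 0), (1, 1), (1, 1), (2, 3), (4, 5)],  # duplicate
            [(0, 0), (1, 1), (np.nan, 2), (2, 3), (4, 5)],  # non-finite
        ],
    )
    def test_invalid_inputs_raise(self, bad):
        with pytest.raises(ConicFitError):
            lc.fit_conic_through_points(bad)

    def test_degenerate_five_point_configuration(self):
        # four collinear points leave the conic underdetermined
        pts = [(0, 0), (1, 0), (2, 0), (3, 0), (1, 1)]
        with pytest.raises(DegenerateConicError):
            lc.fit_conic_through_points(pts)

    def test_large_pixel_coordinates_stay_accurate(self):
        pts = ellipse_points(
            800, 500, 0.4, 5000, 8000, np.radians([10, 80, 150, 220, 300])
        )
        c = lc.fit_conic_through_points(pts)
        assert np.abs(c.evaluate(pts[:, 0], pts[:, 1])).max() <= 1e-9


class TestClassification:
    @pytest.mark.parametrize(
        "coeffs, label",
        [
            ((1, 0, 1, 0, 0, -1), "circle"),
            ((1, 0, 0, 0, -0.5, 0), "parabola"),  # y = x^2
            ((0, 0.5, 0, 0, 0, -1), "hyperbola"),  # x y = 1
            ((1 / 4, 0, 1, 0, 0, -1), "ellipse"),
        ],
    )
    def test_examples(self, coeffs, label):
        c = lc.ConicCoefficients.from_array(coeffs)
        assert lc.classify_conic(c) == label

    def test_degenerate_pair_of_lines(self):
        # x^2 - y^2 = 0 (two crossing lines): full determinant vanishes
        c = lc.ConicCoefficients.from_array([1, 0, -1, 0, 0, 0])
        assert lc.classify_conic(c) == "degenerate"


class TestCanonicalForm:
    def test_unit_circle(self):
        c = lc.ConicCoefficients.from_array([1, 0, 1, 0, 0, -1])
        can = lc.canonical_form(c)
        assert can.center == pytest.approx((0, 0))
        assert can.semi_major == pytest.approx(1)
        assert can.semi_minor == pytest.approx(1)

    def test_axis_aligned_ellipse(self):
        c = lc.ConicCoefficients.from_array([1 / 4, 0, 1, 0, 0, -1])
        can = lc.canonical_form(c)
        assert can.semi_major == pytest.approx(2)
        assert can.semi_minor == pytest.approx(1)
        assert can.orientation == pytest.approx(0)

    def test_rotated_translated_ellipse_by_expansion(self):
        # oracle: coefficients constructed symbolically from the equation
        c = ellipse_coefficients(5, 2, np.radians(30), 3, -2)
        can = lc.canonical_form(c)
        assert can.center[0] == pytest.approx(3, abs=1e-9)
        assert can.center[1] == pytest.approx(-2, abs=1e-9)
        assert can.semi_major == pytest.approx(5, abs=1e-9)
        assert can.semi_minor == pytest.approx(2, abs=1e-9)
        assert can.orientation == pytest.approx(np.radians(30), abs=1e-9)

    def test_non_central_conic_rejected(self):
        parabola = lc.ConicCoefficients.from_array([1, 0, 0, 0, -0.5, 0])
        with pytest.raises(DegenerateConicError):
            lc.canonical_form(parabola)

    def test_imaginary_ellipse_rejected(self):
        # x^2 + y^2 + 1 = 0 has delta < 0 but no real locus
        c = lc.ConicCoefficients.from_array([1, 0, 1, 0, 0, 1])
        with pytest.raises(DegenerateConicError):
            lc.canonical_form(c)


class TestShapeParams:
    def test_circle_has_zero_eccentricity(self):
        c = lc.ConicCoefficients.from_array([1, 0, 1, 0, 0, -1])
        sh = lc.eccentricity(c)
        assert sh.e == 0.0 and sh.q == 0.0 and sh.sf == 1.0

    def test_two_to_one_ellipse(self):
        c = lc.ConicCoefficients.from_array([1 / 4, 0, 1, 0, 0, -1])
        sh = lc.eccentricity(c)
        assert sh.e == pytest.approx(math.sqrt(3) / 2, abs=1e-12)
        assert sh.q == pytest.approx(-0.75, abs=1e-12)
        assert sh.sf == pytest.approx(0.25, abs=1e-12)

    def test_parabola_has_unit_eccentricity(self):
        c = lc.ConicCoefficients.from_array([1, 0, 0, 0, -0.5, 0])
        assert lc.eccentricity(c).e == 1.0

    def test_hyperbola_rejected_as_flagged_shape(self):
        c = lc.ConicCoefficients.from_array([0, 0.5, 0, 0, 0, -1])
        with pytest.raises(UnsupportedShapeError):
            lc.eccentricity(c)

    def test_random_ellipses_recover_closed_form_eccentricity(self):
        # 1000 random ellipses, 5 exact sample points each
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(1000):
            a, b = rng.uniform(1, 10, 2)
            theta = rng.uniform(-np.pi, np.pi)
            cx, cy = rng.uniform(-5, 5, 2)
            pts = ellipse_points(a, b, theta, cx, cy, rng.uniform(0, 2 * np.pi, 5))
            c = lc.fit_conic_through_points(pts)
            e_true = math.sqrt(1 - (min(a, b) / max(a, b)) ** 2)
            worst = max(worst, abs(lc.eccentricity(c).e - e_true))
        assert worst <= 1e-6

    def test_q_sf_coupling_is_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b = rng.uniform(1, 10, 2)
            pts = ellipse_points(a, b, rng.uniform(-1, 1), 0, 0,
                                 rng.uniform(0, 2 * np.pi, 5))
            sh = lc.eccentricity(lc.fit_conic_through_points(pts))
            assert sh.q + 1 == sh.sf  # exact float identity

    def test_eigen_and_invariant_routes_agree(self):
        rng = np.random.default_rng(17)
        for _ in range(2000):
            a, b = rng.uniform(1, 10, 2)
            c = ellipse_coefficients(a, b, rng.uniform(-np.pi, np.pi),
                                     *rng.uniform(-20, 20, 2))
            e_eig = lc.eccentricity(c).e
            e_inv = _eccentricity_invariant(c)
            assert abs(e_eig - e_inv) <= 1e-10 or abs(e_eig**2 - e_inv**2) <= 1e-12


class TestSimilarityInvariance:
    """Eccentricity must not change under scaling/rotation/translation:
    this is what makes fitting in pixel space valid under isotropic
    calibration."""

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        scale=st.floats(0.1, 50),
        rot=st.floats(-3.1, 3.1),
        tx=st.floats(-1000, 1000),
        ty=st.floats(-1000, 1000),
    )
    def test_similarity_transform_preserves_eccentricity(self, scale, rot, tx, ty):
        pts = ellipse_points(4, 1.5, 0.3, 1, -2, np.radians([5, 70, 140, 210, 290]))
        e0 = lc.eccentricity(lc.fit_conic_through_points(pts)).e
        R = np.array([[np.cos(rot), -np.sin(rot)], [np.sin(rot), np.cos(rot)]])
        moved = scale * pts @ R.T + np.array([tx, ty])
        e1 = lc.eccentricity(lc.fit_conic_through_points(moved)).e
        assert abs(e0 - e1) <= 1e-10


def test_noise_robustness_on_wide_arcs():
    """Arcs spanning >= 60 deg of an e=0.7 ellipse, 0.5 px noise, axes of
    hundreds of px: the median eccentricity error stays within 0.05."""
    rng = np.random.default_rng(99)
    e = 0.7
    a = 300.0
    b = a * math.sqrt(1 - e * e)
    errs = []
    for _ in range(1000):
        t0 = rng.uniform(0, 2 * np.pi)
        angles = t0 + np.linspace(0, np.radians(rng.uniform(60, 120)), 5)
        pts = ellipse_points(a, b, 0.2, 50, 80, angles)
        pts = pts + rng.normal(0, 0.5, pts.shape)
        try:
            errs.append(abs(lc.eccentricity(lc.fit_conic_through_points(pts)).e - e))
        except (UnsupportedShapeError, DegenerateConicError):
            errs.append(np.inf)
    assert np.median(errs) <= 0.05


def test_conic_model_results_surface():
    model = lc.ConicModel(UNIT_CIRCLE_PTS)
    res = model.fit()
    assert res.conic_class == "circle"
    assert np.abs(res.residuals).max() <= 1e-9
    assert res.shape.e == 0.0
    text = res.summary()
    assert "circle" in text and "e / Q / SF" in text
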