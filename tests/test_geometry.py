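import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cyanocycle as cc
from cyanocycle.geometry import Contour


def rectangle_contour(length, half_width, n_side=24):
    t = np.linspace(0, 1, n_side, endpoint=False)
    top = np.column_stack([-length / 2 + length * t,
                           np.full(n_side, half_width)])
    right = np.column_stack([np.full(8, length / 2),
                             half_width - 2 * half_width * np.linspace(
                                 0, 1, 8, endpoint=False)])
    bot = np.column_stack([length / 2 - length * t,
                           np.full(n_side, -half_width)])
    left = np.column_stack([np.full(8, -length / 2),
                            -half_width + 2 * half_width * np.linspace(
                                0, 1, 8, endpoint=False)])
    return Contour(np.vstack([top, right, bot, left]))


class TestContourVolume:
    def test_prolate_ellipsoid(self):
        e = cc.ellipse_contour(semi_major=2.0, semi_minor=1.0,
                               orientation=0.3, n_points=128)
        expected = 4.0 / 3.0 * math.pi * 2.0 * 1.0 ** 2
        assert cc.contour_volume(e) == pytest.approx(expected, rel=0.01)

    def test_sphere(self):
        c = cc.ellipse_contour(semi_major=1.0, semi_minor=1.0, n_points=128)
        assert cc.contour_volume(c) == pytest.approx(4 * math.pi / 3,
                                                     rel=0.01)

    def test_cylinder_from_rectangle(self):
        L, r = 4.0, 1.0
        rect = rectangle_contour(L, r)
        assert cc.contour_volume(rect) == pytest.approx(math.pi * r ** 2 * L,
                                                        rel=0.02)

    def test_slice_convergence(self):
        e = cc.ellipse_contour(semi_major=1.5, semi_minor=1.0,
                               orientation=1.1, n_points=128)
        v200 = cc.contour_volume(e, n_slices=200)
        v400 = cc.contour_volume(e, n_slices=400)
        assert abs(v400 - v200) / v200 < 0.005

    def test_too_few_slices_rejected(self):
        e = cc.ellipse_contour()
        with pytest.raises(ValueError):
            cc.contour_volume(e, n_slices=5)

    def test_degenerate_contour_rejected(self):
        line = np.column_stack([np.linspace(0, 1, 10), np.zeros(10)])
        with pytest.raises(ValueError):
            Contour(line)

    @given(angle=st.floats(0, math.pi), dx=st.floats(-5, 5),
           dy=st.floats(-5, 5))
    def test_rigid_transform_invariance(self, angle, dx, dy):
        base = cc.ellipse_contour(semi_major=1.8, semi_minor=1.1,
                                  n_points=64)
        v0 = cc.contour_volume(base)
        r0 = cc.shape_summary(base).axis_ratio
        c, s = math.cos(angle), math.sin(angle)
        pts = base.points @ np.array([[c, s], [-s, c]]) + (dx, dy)
        moved = Contour(pts)
        assert cc.contour_volume(moved) == pytest.approx(v0, rel=1e-6)
        assert cc.shape_summary(moved).axis_ratio == pytest.approx(r0,
                                                                   rel=1e-6)

    @given(scale=st.floats(0.2, 5.0))
    def test_scaling_law(self, scale):
        base = cc.ellipse_contour(semi_major=1.5, semi_minor=0.9,
                                  n_points=64)
        scaled = Contour(base.points * scale)
        assert cc.contour_volume(scaled) == pytest.approx(
            cc.contour_volume(base) * scale ** 3, rel=1e-6)
        assert cc.shape_summary(scaled).axis_ratio == pytest.approx(
            cc.shape_summary(base).axis_ratio, rel=1e-6)


class TestShapeSummary:
    def test_circle_ratio_one(self):
        c = cc.ellipse_contour(semi_major=1.0, semi_minor=1.0, n_points=64)
        assert cc.shape_summary(c).axis_ratio == pytest.approx(1.0, abs=1e-6)

    def test_two_to_one_ellipse(self):
        e = cc.ellipse_contour(semi_major=2.0, semi_minor=1.0, n_points=256)
        s = cc.shape_summary(e)
        assert s.axis_ratio == pytest.approx(0.5, abs=1e-4)
        assert s.major_axis_length == pytest.approx(4.0, rel=1e-3)

    def test_birth_shape_ratio(self):
        e = cc.ellipse_contour(semi_major=1.0, semi_minor=0.77, n_points=256)
        assert cc.shape_summary(e).axis_ratio == pytest.approx(0.77,
                                                               abs=0.01)

    def test_orientation_recovered(self):
        e = cc.ellipse_contour(semi_major=2.0, semi_minor=1.0,
                               orientation=0.7, n_points=128)
        assert cc.shape_summary(e).orientation == pytest.approx(0.7,
                                                                abs=1e-3)


class TestDaughterRatio:
    def test_measured_division_ratio(self):
        """A mother dividing at ratio 0.63 yields daughters at 0.79."""
        assert round(cc.predicted_daughter_ratio(0.63), 2) == 0.79

    def test_fixed_point(self):
        x = 1 / math.sqrt(2)
        assert cc.predicted_daughter_ratio(x) == pytest.approx(x, rel=1e-12)

    def test_hemisected_two_to_one(self):
        assert cc.predicted_daughter_ratio(0.5) == pytest.approx(1.0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cc.predicted_daughter_ratio(0.0)
        with pytest.raises(ValueError):
            cc.predicted_daughter_ratio(1.2)

    def test_eccentricity_cycle_closes(self):
        """Division at the measured ratio predicts a birth ratio inside the
        measured 0.77 ± 0.04 band, consistent with perpendicular division
        planes."""
        predicted_birth = cc.predicted_daughter_ratio(0.63)
        assert abs(predicted_birth - 0.77) < 0.04


class TestDivisionAngle:
    def _shape(self, orientation, ratio=0.7):
        e = cc.ellipse_contour(semi_major=1.5, semi_minor=ratio * 1.5,
                               orientation=orientation, n_points=64)
        return cc.shape_summary(e)

    def test_perpendicular(self):
        ang = cc.division_angle(self._shape(0.0), self._shape(math.pi / 2))
        assert ang.degrees == pytest.approx(90.0, abs=1e-6)
        assert ang.is_perpendicular and ang.defined

    def test_parallel(self):
        ang = cc.division_angle(self._shape(0.3), self._shape(0.3))
        assert ang.degrees == pytest.approx(0.0, abs=1e-6)
        assert not ang.is_perpendicular

    def test_circle_orientation_undefined(self):
        ang = cc.division_angle(self._shape(0.0, ratio=1.0),
                                self._shape(0.5))
        assert not ang.defined
        assert math.isnan(ang.degrees)
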