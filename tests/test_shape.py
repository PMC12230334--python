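"""Shape descriptors: contour, roundness, volume, surface area, MCI*."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import sicmorph as sm
from sicmorph.shape import IRREGULAR, SPHERICAL, DegeneratePolygonError

from conftest import flat_topography


def plateau(shape, region, height=1000.0, pitch=10.0):
    values = np.zeros(shape)
    values[region] = height
    t = flat_topography(values, pitch=pitch)
    return t, sm.segment_object(t)


class TestContour:
    def test_disc_perimeter_matches_circle(self):
        # flat cylinder of radius 500 nm on a 5 nm grid
        yy, xx = np.mgrid[0:220, 0:220]
        rho = np.hypot((xx - 110) * 5.0, (yy - 110) * 5.0)
        t = flat_topography(np.where(rho <= 500.0, 1000.0, 0.0), pitch=5.0)
        poly = sm.contour_polygon(t, sm.segment_object(t), level=0.5)
        assert poly.perimeter == pytest.approx(2 * math.pi * 500.0, rel=0.01)
        assert not poly.border_clipped

    def test_square_plateau_perimeter(self):
        t, mask = plateau((60, 60), (slice(10, 50), slice(10, 50)), pitch=10.0)
        poly = sm.contour_polygon(t, mask, level=0.5)
        assert poly.perimeter == pytest.approx(4 * 400.0, rel=0.02)

    def test_single_pixel_mask_is_degenerate(self):
        values = np.zeros((9, 9))
        values[4, 4] = 500.0
        t = flat_topography(values)
        mask = sm.ObjectMask(values > 0)
        with pytest.raises(DegeneratePolygonError):
            sm.contour_polygon(t, mask)

    def test_border_clipped_object_is_flagged(self):
        yy, xx = np.mgrid[0:60, 0:60]
        rho = np.hypot((xx - 55) * 10.0, (yy - 30) * 10.0)
        t = flat_topography(np.where(rho <= 250.0, 800.0, 0.0), pitch=10.0)
        poly = sm.contour_polygon(t, sm.segment_object(t), level=0.5)
        assert poly.border_clipped


class TestRoundness:
    def test_circle_is_one(self):
        rho = 700.0
        assert sm.roundness(math.pi * rho**2, 2 * math.pi * rho) == pytest.approx(1.0)

    def test_square_closed_form(self):
        s = 123.0
        assert sm.roundness(s**2, 4 * s) == pytest.approx(2 / math.sqrt(math.pi), rel=1e-12)

    def test_four_to_one_ellipse(self):
        # Ramanujan approximation as independent perimeter oracle
        a, b = 4.0, 1.0
        h = ((a - b) / (a + b)) ** 2
        p = math.pi * (a + b) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h)))
        R = sm.roundness(math.pi * a * b, p)
        assert R == pytest.approx(1.365, abs=0.005)
        # cross-check against a measured contour of an elliptical plateau
        yy, xx = np.mgrid[0:120, 0:420]
        inside = ((xx - 210) / 200.0) ** 2 + ((yy - 60) / 50.0) ** 2 <= 1.0
        t = flat_topography(np.where(inside, 1000.0, 0.0), pitch=4.0)
        poly = sm.contour_polygon(t, sm.segment_object(t), level=0.5)
        assert sm.roundness(poly.area, poly.perimeter) == pytest.approx(R, rel=0.01)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sm.roundness(0.0, 5.0)


class TestClassification:
    @pytest.mark.parametrize(
        "R,expected",
        [(1.0, SPHERICAL), (1.15, SPHERICAL), (0.85, SPHERICAL), (1.20, IRREGULAR)],
    )
    def test_fifteen_percent_rule(self, R, expected):
        assert sm.classify_shape(R) == expected

    @given(st.floats(0.01, 3.0), st.floats(0.01, 3.0))
    def test_monotone_in_deviation(self, r1, r2):
        lo, hi = sorted([r1, r2], key=lambda r: abs(r - 1))
        if sm.classify_shape(lo) == IRREGULAR:
            assert sm.classify_shape(hi) == IRREGULAR


class TestVolumeSurface:
    def test_single_pixel_volume(self):
        values = np.zeros((8, 8))
        values[3:5, 3:5] = 0.0
        values[4, 4] = 700.0
        t = flat_topography(values, pitch=10.0)
        mask = sm.ObjectMask(values > 0)
        assert sm.volume(t, mask) == pytest.approx(10.0 * 10.0 * 700.0)

    def test_volume_scales_with_pitch(self):
        values = np.zeros((10, 10))
        values[3:7, 3:7] = 400.0
        mask = sm.ObjectMask(values > 0)
        v1 = sm.volume(flat_topography(values, pitch=10.0), mask)
        t2 = sm.Topography(values, pitch_x=20.0, pitch_y=10.0)
        assert sm.volume(t2, mask) == pytest.approx(2 * v1)

    def test_hemisphere_volume_converges(self, hemisphere):
        t, mask = hemisphere
        assert sm.volume(t, mask) == pytest.approx((2 / 3) * math.pi * 500.0**3, rel=0.01)

    def test_flat_plateau_interior_cells(self):
        t, mask = plateau((30, 30), (slice(5, 25), slice(5, 25)), pitch=10.0)
        # 20x20 mask: cells with >=1 vertex span a 21x21 vertex block -> 21^2-... :
        # included cells form a 21x21 cell square minus nothing = 441 cells; the
        # 19x19 interior cells are flat and contribute dx*dy each, edge cells add
        # the vertical side walls.
        sa = sm.surface_area(t, mask)
        flat_part = 19 * 19 * 100.0
        assert sa > flat_part
        interior = sm.ObjectMask(np.pad(np.ones((18, 18), bool), 6)[:30, :30])
        # fully interior region of the plateau: exactly area * dx*dy
        sa_int = sm.surface_area(t, interior)
        assert sa_int == pytest.approx(19 * 19 * 100.0)

    def test_tilted_plane_closed_form(self):
        theta = math.radians(30.0)
        yy, xx = np.mgrid[0:40, 0:40]
        values = math.tan(theta) * xx * 10.0
        t = flat_topography(values, pitch=10.0)
        mask = sm.ObjectMask(np.ones((40, 40), bool))
        sa = sm.surface_area(t, mask)
        assert sa == pytest.approx(39 * 39 * 100.0 / math.cos(theta), rel=1e-9)

    def test_hemisphere_surface_converges(self, hemisphere):
        t, mask = hemisphere
        assert sm.surface_area(t, mask) == pytest.approx(2 * math.pi * 500.0**2, rel=0.015)

    def test_empty_cells_error(self):
        t = flat_topography(np.full((3, 3), np.nan))
        mask = sm.ObjectMask(np.ones((3, 3), bool))
        with pytest.raises(sm.TopographyError):
            sm.surface_area(t, mask)


class TestMciStar:
    def test_sphere_is_exactly_one(self):
        r = 873.0
        assert sm.mci_star(4 * math.pi * r**2, (4 / 3) * math.pi * r**3) == pytest.approx(1.0, abs=1e-12)

    def test_hemisphere_closed_form(self):
        r = 500.0
        val = sm.mci_star(2 * math.pi * r**2, (2 / 3) * math.pi * r**3)
        assert val == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    @given(st.floats(0.1, 10.0))
    def test_scale_invariant(self, lam):
        sa, v = 3.7e6, 8.1e8
        assert sm.mci_star(sa * lam**2, v * lam**3) == pytest.approx(sm.mci_star(sa, v), rel=1e-9)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            sm.mci_star(-1.0, 1.0)


class TestSizeDescriptors:
    def test_plateau_row_extent(self):
        values = np.zeros((30, 30))
        values[10:20, 5:25] = 600.0
        t = sm.Topography(values, pitch_x=10.0, pitch_y=20.0)
        mask = sm.ObjectMask(values > 0)
        d = sm.size_descriptors(t, mask)
        assert d.d_slow == pytest.approx(200.0)
        assert d.h_max == pytest.approx(600.0)

    def test_hemisphere_equivalent_sphere(self, hemisphere):
        t, mask = hemisphere
        d = sm.size_descriptors(t, mask)
        assert d.d_sphere_equiv == pytest.approx(4 ** (1 / 3) * 500.0, rel=0.01)
        assert d.d_circle_equiv == pytest.approx(1000.0, rel=0.02)


class TestShapeReport:
    def test_hemisphere_report(self, hemisphere):
        t, mask = hemisphere
        rep = sm.shape_report(t, mask)
        assert rep.shape_class == SPHERICAL
        assert rep.mci_star == pytest.approx(1 / math.sqrt(2), abs=0.02)
        assert rep.roundness_R == pytest.approx(1.0, abs=0.01)
        assert rep.circle_perimeter_p == pytest.approx(2 * math.sqrt(math.pi * rep.area_A))

    def test_three_lobe_blob_is_irregular(self):
        t = sm.make_irregular(160, 160, 25.0, 900.0, 1600.0, n_lobes=3, seed=4)
        mask = sm.segment_object(t, rel_threshold=0.05)
        rep = sm.shape_report(t, mask)
        assert rep.shape_class == IRREGULAR
        assert rep.roundness_R > 1.15
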