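"""Cumulative range reconstruction from presence-only locality points.

Past ranges are extents of occurrence built backwards in time: the
modern expert-drawn polygon is the baseline for the historical range,
and the completed historical range is the baseline for the Holocene
range.  Each older locality point falling outside the baseline is
connected to its two nearest admissible features — other outside points
of the same layer, the nearest part of the baseline polygon, or (when
fewer than two such features exist) the study-region border — and the
connection is realised as the triangle spanned by the point and its two
anchors.  Unioning baseline and attachment triangles, dissolving, and
clipping to the border yields the period range.  Because construction is
cumulative, ranges are strictly nested in time and a species' area can
only shrink towards the present.

All geometry here lives in the equal-area plane (km), so shapely areas
are km^2 directly.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from shapely.geometry import (
    GeometryCollection,
    LineString,
    MultiPolygon,
    Point,
    Polygon,
)
from shapely.geometry.base import BaseGeometry
from shapely.ops import nearest_points, unary_union
from shapely.validation import make_valid

from .io_core import LocalityRecord
from .periods import TimePeriod
from .projection import EqualAreaProjection

logger = logging.getLogger(__name__)


class FeatureKind(enum.IntEnum):
    """Kinds of attachment anchors, in deterministic tie-break order."""

    POINT = 0
    POLYGON = 1
    BORDER = 2


@dataclass(frozen=True)
class Anchor:
    kind: FeatureKind
    geometry: Point  # the anchor point itself (e.g. nearest point on boundary)
    feature_id: str  # site id for points; "baseline"/"border" otherwise
    distance: float


@dataclass
class BorderGeometry:
    """The study-region border polygon and its boundary polyline."""

    polygon: BaseGeometry

    def __post_init__(self):
        if not self.polygon.is_valid:
            self.polygon = make_valid(self.polygon)
        if not self.polygon.is_valid:  # pragma: no cover
            raise ValueError("border polygon unrepairable")

    @property
    def boundary(self) -> BaseGeometry:
        return self.polygon.boundary

    @property
    def diameter(self) -> float:
        minx, miny, maxx, maxy = self.polygon.bounds
        return float(((maxx - minx) ** 2 + (maxy - miny) ** 2) ** 0.5)


@dataclass
class AttachmentResult:
    point: Point
    point_id: str
    anchor_1: Anchor
    anchor_2: Anchor
    polygon: BaseGeometry = field(default=None)  # filled by attachment_polygon


@dataclass
class RangeSet:
    """One species x period range with its equal-area km^2 area."""

    species_id: str
    period: TimePeriod
    geometry: BaseGeometry  # multipolygon in the equal-area plane
    crs_tag: str
    area_km2: float


def project_equal_area(
    geometry: BaseGeometry, projection: EqualAreaProjection
) -> BaseGeometry:
    """Project WGS84 geometry into the equal-area plane (km units)."""
    return projection.project_geometry(geometry)


def _nearest_part(baseline: BaseGeometry, point: Point) -> BaseGeometry:
    """Nearest single polygon part of a (multi)polygon baseline."""
    if isinstance(baseline, (MultiPolygon, GeometryCollection)):
        parts = [g for g in baseline.geoms if isinstance(g, Polygon) and not g.is_empty]
        if not parts:
            return baseline
        return min(parts, key=lambda g: g.distance(point))
    return baseline


def nearest_two_features(
    point: Point,
    other_points: dict[str, Point],
    baseline: BaseGeometry,
    border: BorderGeometry,
) -> tuple[Anchor, Anchor]:
    """The two nearest admissible features for a locality point.

    Candidates are the other outside points of the layer (each its own
    feature) and the nearest part of the baseline polygon (anchored at
    the closest point of its boundary).  When fewer than two such
    features exist the border polyline supplies the missing anchor, at
    the foot of the perpendicular (the nearest boundary point).  Ties
    break deterministically by distance, then feature kind
    (point < polygon < border), then feature id.
    """
    candidates: list[Anchor] = []
    for pid, p in other_points.items():
        if p.equals_exact(point, 0.0):
            continue
        candidates.append(Anchor(FeatureKind.POINT, p, pid, point.distance(p)))
    if baseline is not None and not baseline.is_empty:
        part = _nearest_part(baseline, point)
        on_poly = nearest_points(part.exterior if isinstance(part, Polygon) else part, point)[0]
        candidates.append(
            Anchor(FeatureKind.POLYGON, on_poly, "baseline", point.distance(on_poly))
        )
    if len(candidates) < 2:
        foot = nearest_points(border.boundary, point)[0]
        candidates.append(
            Anchor(FeatureKind.BORDER, foot, "border", point.distance(foot))
        )
    candidates.sort(key=lambda a: (a.distance, a.kind, a.feature_id))
    return candidates[0], candidates[1]


def attachment_polygon(result: AttachmentResult, epsilon: float) -> BaseGeometry:
    """Realise a point-to-anchors connection as an areal polygon.

    The triangle (point, anchor_1, anchor_2) is the smallest-area polygon
    consistent with connecting the point to both features.  Collinear or
    otherwise degenerate triangles are replaced by the two connecting
    segments buffered by ``epsilon`` so every connection contributes
    positive area; a point coinciding with both anchors contributes
    nothing.
    """
    p = result.point
    a1, a2 = result.anchor_1.geometry, result.anchor_2.geometry
    tri = Polygon([(p.x, p.y), (a1.x, a1.y), (a2.x, a2.y)])
    if tri.area > 0 and tri.is_valid:
        return tri
    segs = [
        LineString([p, a]) for a in (a1, a2) if p.distance(a) > 0
    ]
    if not segs:
        logger.info("attachment for %s degenerate (anchors coincide with point)", result.point_id)
        return Polygon()
    return unary_union([s.buffer(epsilon, quad_segs=4) for s in segs])


@dataclass
class ReconstructionConfig:
    projection: EqualAreaProjection = field(default_factory=EqualAreaProjection)
    #: degenerate-attachment buffer as a fraction of the border diameter
    epsilon_fraction: float = 1e-6


def build_period_range(
    baseline: BaseGeometry,
    points: list[LocalityRecord],
    border: BorderGeometry,
    config: ReconstructionConfig | None = None,
    species_id: str = "",
    period: TimePeriod = TimePeriod.HOLOCENE,
) -> RangeSet:
    """Build one temporal layer from a baseline plus older locality points.

    ``baseline`` and ``border`` must already be in the equal-area plane;
    ``points`` are WGS84 locality records and are projected here.  All
    attachments are computed against the original baseline (not the
    incrementally grown geometry), so the union is independent of point
    order; points are nevertheless processed in sorted order for
    reproducible logs.
    """
    config = config or ReconstructionConfig()
    proj = config.projection
    eps = config.epsilon_fraction * border.diameter

    projected: dict[str, Point] = {}
    for rec in sorted(points, key=lambda r: (r.site_id, r.species_id)):
        x, y = proj.forward(rec.lon, rec.lat)
        projected[rec.site_id] = Point(float(x), float(y))
    outside = {
        pid: p for pid, p in projected.items() if baseline.is_empty or not baseline.covers(p)
    }

    pieces: list[BaseGeometry] = [] if baseline.is_empty else [baseline]
    for pid in sorted(outside):
        p = outside[pid]
        others = {k: v for k, v in outside.items() if k != pid}
        a1, a2 = nearest_two_features(p, others, baseline, border)
        result = AttachmentResult(point=p, point_id=pid, anchor_1=a1, anchor_2=a2)
        poly = attachment_polygon(result, eps)
        if not poly.is_empty:
            pieces.append(poly)
        # isolated points with degenerate attachments still need area
        if poly.is_empty or not poly.covers(p):
            pieces.append(p.buffer(eps, quad_segs=4))

    merged = unary_union(pieces) if pieces else Polygon()
    merged = merged.intersection(border.polygon)
    if not merged.is_empty and not merged.is_valid:
        merged = make_valid(merged)
        if not merged.is_valid:  # pragma: no cover
            raise ValueError(f"{species_id}/{period.value}: invalid union result")
    merged = _dissolve(merged)
    return RangeSet(
        species_id=species_id,
        period=period,
        geometry=merged,
        crs_tag=proj.crs_tag,
        area_km2=range_area_km2_from_geometry(merged),
    )


def _dissolve(geom: BaseGeometry) -> BaseGeometry:
    """Drop interior rings: polygons contained in larger ones dissolve."""
    if isinstance(geom, Polygon):
        return Polygon(geom.exterior)
    if isinstance(geom, MultiPolygon):
        return MultiPolygon([Polygon(g.exterior) for g in geom.geoms])
    if isinstance(geom, GeometryCollection):
        polys = [g for g in geom.geoms if isinstance(g, (Polygon, MultiPolygon))]
        return _dissolve(unary_union(polys)) if polys else Polygon()
    return geom


def range_area_km2_from_geometry(geometry: BaseGeometry) -> float:
    return float(geometry.area)


def range_area_km2(range_set: RangeSet) -> float:
    """Planar area of a projected range, km^2 (multipart areas summed)."""
    if not range_set.crs_tag.startswith("cea:"):
        raise ValueError("range geometry is not in the equal-area plane")
    return range_area_km2_from_geometry(range_set.geometry)


def proportion_lost(area_old: float, area_new: float) -> float:
    """Fraction of the older range lost by the newer period.

    Cumulative construction guarantees ``area_new <= area_old``; a zero
    older area is undefined and the species must be flagged upstream.
    """
    if area_old <= 0:
        raise ValueError("proportion lost undefined for zero older-period area")
    if area_new > area_old * (1 + 1e-9):
        raise ValueError("newer area exceeds older area; ranges are not nested")
    return min(max((area_old - area_new) / area_old, 0.0), 1.0)


def build_species_ranges(
    species_id: str,
    modern_geom: BaseGeometry,
    historical_points: list[LocalityRecord],
    holocene_points: list[LocalityRecord],
    border: BorderGeometry,
    config: ReconstructionConfig | None = None,
    extinct_part: BaseGeometry | None = None,
) -> dict[TimePeriod, RangeSet]:
    """Build the full modern -> historical -> Holocene chain for one species.

    ``modern_geom`` and ``extinct_part`` are WGS84; extinct-range parts
    carved out of the modern map are merged into the historical baseline
    before point attachment.
    """
    config = config or ReconstructionConfig()
    proj = config.projection
    modern = make_valid(proj.project_geometry(modern_geom)).intersection(border.polygon)
    ranges = {
        TimePeriod.MODERN: RangeSet(
            species_id,
            TimePeriod.MODERN,
            _dissolve(modern),
            proj.crs_tag,
            range_area_km2_from_geometry(_dissolve(modern)),
        )
    }
    hist_base = modern
    if extinct_part is not None and not extinct_part.is_empty:
        hist_base = unary_union(
            [modern, make_valid(proj.project_geometry(extinct_part)).intersection(border.polygon)]
        )
    hist = build_period_range(
        hist_base, historical_points, border, config, species_id, TimePeriod.HISTORICAL
    )
    ranges[TimePeriod.HISTORICAL] = hist
    hol_points = holocene_points + historical_points  # cumulative layers
    hol = build_period_range(
        hist.geometry, hol_points, border, config, species_id, TimePeriod.HOLOCENE
    )
    ranges[TimePeriod.HOLOCENE] = hol
    return ranges
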