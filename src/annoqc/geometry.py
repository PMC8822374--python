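"""Exact polygon geometry: areas, unions, Jaccard similarity, unit conversion.

All computation is exact polygon clipping (shapely/GEOS), never
rasterisation, so the Jaccard similarity index (JSI) of two annotators'
regions is resolution-independent.  Circles are buffered to 64-gon
approximations before any clipping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box as shapely_box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .model import AnnotationRecord

CIRCLE_SEGMENTS = 64


@dataclass
class RegionSet:
    """All polygons one annotator drew for one label on one slide."""

    polygons: list[list[tuple[float, float]]] = field(default_factory=list)
    label: str = ""
    annotator_id: str = ""
    slide_id: str = ""

    def union(self) -> BaseGeometry:
        return unary_union([Polygon(ring) for ring in self.polygons])


def ring_area(ring: Sequence[tuple[float, float]]) -> float:
    """Area of a polygon ring in px^2 (absolute shoelace value).

    Orientation-independent; raises on rings with fewer than 3 distinct
    vertices or zero area.
    """
    pts = list(dict.fromkeys((float(x), float(y)) for x, y in ring))
    if len(pts) < 3:
        raise ValueError("degenerate ring: fewer than 3 distinct vertices")
    area = Polygon(ring).area
    if area == 0.0:
        raise ValueError("degenerate ring: zero area")
    return area


def px2_to_mm2(area_px2: float, mpp: float) -> float:
    """Convert an area from px^2 to mm^2 given microns-per-pixel."""
    if mpp <= 0:
        raise ValueError("microns_per_pixel must be positive")
    return area_px2 * (mpp / 1000.0) ** 2


def circle_polygon(
    centre: tuple[float, float], radius_px: float, segments: int = CIRCLE_SEGMENTS
) -> Polygon:
    """Regular-polygon approximation of a circle for clipping operations."""
    return Point(centre).buffer(radius_px, quad_segs=segments // 4)


def record_geometry(rec: AnnotationRecord) -> Optional[BaseGeometry]:
    """Areal shapely geometry of a record, or None for non-areal constructs."""
    if rec.construct == "polygon":
        return Polygon(rec.geometry)
    if rec.construct == "bounding_box":
        x0, y0, x1, y1 = rec.box_corners()
        return shapely_box(x0, y0, x1, y1)
    if rec.construct == "circle":
        return circle_polygon(rec.geometry[0], rec.radius_px)
    return None


def union_area(regions: RegionSet) -> float:
    """Area of the set-union of the polygons (overlaps counted once)."""
    if not regions.polygons:
        return 0.0
    return regions.union().area


def jaccard(a: RegionSet, b: RegionSet) -> float:
    """Jaccard similarity index of two annotators' label-unions.

    JSI = area(A intersect B) / area(A union B) over the per-annotator
    unions.  By convention, two empty sets have JSI 1.0 and an empty set
    against a non-empty one has JSI 0.0 (the index is otherwise undefined
    at 0/0).  Symmetric in its arguments.
    """
    geom_a = a.union() if a.polygons else None
    geom_b = b.union() if b.polygons else None
    if geom_a is None and geom_b is None:
        return 1.0
    if geom_a is None or geom_b is None:
        return 0.0
    inter = geom_a.intersection(geom_b).area
    union = geom_a.union(geom_b).area
    if union == 0.0:
        return 1.0
    return inter / union


def polygon_jaccard(
    ring_a: Sequence[tuple[float, float]], ring_b: Sequence[tuple[float, float]]
) -> float:
    """Per-polygon JSI variant (one ring against one ring)."""
    return jaccard(
        RegionSet(polygons=[list(ring_a)]), RegionSet(polygons=[list(ring_b)])
    )


def raster_jaccard(
    a: RegionSet, b: RegionSet, grid: float = 0.05
) -> float:
    """Rasterisation estimate of the JSI on a square pixel grid.

    Counts grid-cell centres inside each union.  Used as an independent
    cross-check of the exact clipping path; accuracy is limited by the
    grid resolution.
    """
    from shapely import contains_xy

    geom_a = a.union() if a.polygons else None
    geom_b = b.union() if b.polygons else None
    if geom_a is None and geom_b is None:
        return 1.0
    if geom_a is None or geom_b is None:
        return 0.0
    minx = min(geom_a.bounds[0], geom_b.bounds[0]) - grid
    miny = min(geom_a.bounds[1], geom_b.bounds[1]) - grid
    maxx = max(geom_a.bounds[2], geom_b.bounds[2]) + grid
    maxy = max(geom_a.bounds[3], geom_b.bounds[3]) + grid
    xs = np.arange(minx + grid / 2, maxx, grid)
    ys = np.arange(miny + grid / 2, maxy, grid)
    gx, gy = np.meshgrid(xs, ys)
    in_a = contains_xy(geom_a, gx.ravel(), gy.ravel())
    in_b = contains_xy(geom_b, gx.ravel(), gy.ravel())
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 1.0
    return np.count_nonzero(in_a & in_b) / union
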