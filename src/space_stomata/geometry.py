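"""Planar geometric primitives for epidermal point-pattern analysis.

All coordinates are in micrometres (µm), matching confocal segmentation
exports.  Polygons (cotyledon and sector outlines) are simple closed rings;
derived regions (offset rings, clipped unions) may be multi-part and carry
holes.  Shapely 2.x provides the computational geometry; this module fixes
the conventions that matter for density accounting:

* outlines are normalized counter-clockwise on construction;
* a point exactly on a boundary counts as *inside*;
* outline dilation is a true Euclidean (Minkowski-disk) dilation, so every
  point of the offset region is within ``d`` of the original closed region;
* distances are measured to boundary *segments*, never to sampled vertices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPolygon, Point, Polygon
from shapely.ops import unary_union

__all__ = [
    "InvalidGeometryError",
    "PlacementError",
    "Outline",
    "Region",
    "polygon_area",
    "point_in_polygon",
    "nearest_boundary_distance",
    "boundary_distances",
    "points_in_geometry",
    "dilate_outline",
    "clip_subtract",
    "union_regions",
    "transpose_outline",
]

#: vertices per full circle when polygonizing disk Minkowski sums
CIRCLE_SEGMENTS = 64


class InvalidGeometryError(ValueError):
    """Raised for degenerate outlines (too few vertices, zero area, self-intersection)."""


class PlacementError(RuntimeError):
    """Raised when a random rigid placement cannot be found inside the window."""


@dataclass(frozen=True)
class Outline:
    """A simple closed polygon ring (first vertex stored once, not repeated).

    Vertex order is normalized to counter-clockwise; the input order of the
    ring is otherwise preserved so that digitized outlines keep their shape.
    """

    vertices: np.ndarray  # (n, 2) float array, µm

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise InvalidGeometryError("outline vertices must be an (n, 2) array")
        if not np.all(np.isfinite(v)):
            raise InvalidGeometryError("outline vertices must be finite")
        # drop a repeated closing vertex if present
        if len(v) > 1 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise InvalidGeometryError("outline needs at least 3 distinct vertices")
        signed = _signed_area(v)
        if abs(signed) <= 0.0:
            raise InvalidGeometryError("outline has zero area")
        if signed < 0:  # normalize to counter-clockwise
            v = v[::-1]
        poly = Polygon(v)
        if not poly.is_valid:
            raise InvalidGeometryError("outline is self-intersecting or otherwise invalid")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "_polygon", poly)

    @property
    def polygon(self) -> Polygon:
        """The shapely polygon for this outline."""
        return self._polygon  # type: ignore[attr-defined]

    @property
    def area(self) -> float:
        return self._polygon.area  # type: ignore[attr-defined]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self._polygon.bounds  # type: ignore[attr-defined]

    @classmethod
    def from_points(cls, pts: Iterable[Sequence[float]]) -> "Outline":
        return cls(np.asarray(list(pts), dtype=float))


@dataclass(frozen=True)
class Region:
    """A planar area: possibly multi-part, possibly with holes, possibly empty.

    Thin wrapper over a shapely (Multi)Polygon with exact area accounting.
    """

    geom: shapely.Geometry = field(default_factory=lambda: Polygon())

    def __post_init__(self) -> None:
        g = self.geom
        if isinstance(g, Outline):
            g = g.polygon
        if not isinstance(g, (Polygon, MultiPolygon)):
            g = _to_polygonal(g)
        object.__setattr__(self, "geom", g)

    @property
    def area(self) -> float:
        return self.geom.area

    @property
    def is_empty(self) -> bool:
        return self.geom.is_empty

    def covers_point(self, x: float, y: float) -> bool:
        """True iff (x, y) is in the closed region (boundary counts in)."""
        return bool(shapely.intersects_xy(self.geom, x, y))

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        """Vectorized closed-region membership for an (n, 2) array."""
        xy = np.asarray(xy, dtype=float).reshape(-1, 2)
        return shapely.intersects_xy(self.geom, xy[:, 0], xy[:, 1])

    @classmethod
    def empty(cls) -> "Region":
        return cls(Polygon())


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _to_polygonal(geom: shapely.Geometry) -> Polygon | MultiPolygon:
    """Keep only the polygonal part of a geometry (drops slivers of lower dimension)."""
    if geom.is_empty:
        return Polygon()
    if isinstance(geom, (Polygon, MultiPolygon)):
        return geom
    polys = [g for g in getattr(geom, "geoms", []) if isinstance(g, (Polygon, MultiPolygon))]
    if not polys:
        return Polygon()
    merged = unary_union(polys)
    return merged if isinstance(merged, (Polygon, MultiPolygon)) else Polygon()


def polygon_area(outline: Outline) -> float:
    """Area enclosed by an outline (µm²), independent of vertex orientation."""
    return outline.area


def point_in_polygon(p: Sequence[float], outline: Outline) -> bool:
    """True iff ``p`` is inside the outline or exactly on its boundary."""
    x, y = float(p[0]), float(p[1])
    return bool(shapely.intersects_xy(outline.polygon, x, y))


def nearest_boundary_distance(p: Sequence[float], outline: Outline) -> float:
    """Minimum Euclidean distance from a point to the outline's boundary.

    Measured against boundary segments (zero iff the point is on the
    boundary); the point may lie inside or outside.
    """
    return float(outline.polygon.exterior.distance(Point(float(p[0]), float(p[1]))))


def boundary_distances(xy: np.ndarray, geom: shapely.Geometry | Outline | Region) -> np.ndarray:
    """Vectorized distances from points to the boundary of a geometry.

    ``geom`` may be an Outline, a Region, or any shapely geometry; distance
    is to its boundary, so points inside get their depth, not zero.
    """
    if isinstance(geom, Outline):
        g = geom.polygon
    elif isinstance(geom, Region):
        g = geom.geom
    else:
        g = geom
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    pts = shapely.points(xy)
    return shapely.distance(pts, g.boundary)


def points_in_geometry(xy: np.ndarray, geom: shapely.Geometry | Outline | Region) -> np.ndarray:
    """Vectorized closed-set membership (boundary counts as inside)."""
    if isinstance(geom, Outline):
        g = geom.polygon
    elif isinstance(geom, Region):
        g = geom.geom
    else:
        g = geom
    xy = np.asarray(xy, dtype=float).reshape(-1, 2)
    return shapely.intersects_xy(g, xy[:, 0], xy[:, 1])


def dilate_outline(outline: Outline, d: float, circle_segments: int = CIRCLE_SEGMENTS) -> Region:
    """Euclidean dilation of the closed region by a disk of radius ``d``.

    Minkowski sum with a disk: every point of the result is within ``d`` of
    the original closed region and vice versa, up to the polygonization of
    the disk (``circle_segments`` vertices per full circle). ``d = 0``
    returns the original outline as a Region.
    """
    if d < 0:
        raise ValueError(f"dilation distance must be non-negative, got {d}")
    if d == 0:
        return Region(outline.polygon)
    quad_segs = max(1, circle_segments // 4)
    return Region(outline.polygon.buffer(d, quad_segs=quad_segs))


def clip_subtract(region: Region, keep_within: Outline, remove: Sequence[Region] = ()) -> Region:
    """Intersect ``region`` with ``keep_within`` and subtract the union of ``remove``.

    The result may be empty (area 0); multi-part results and holes are kept.
    """
    g = region.geom.intersection(keep_within.polygon)
    if remove:
        g = g.difference(unary_union([r.geom for r in remove]))
    return Region(_to_polygonal(g))


def union_regions(regions: Sequence[Region]) -> Region:
    """Union of regions; overlapping parts are counted once. Empty list → empty Region."""
    if not regions:
        return Region.empty()
    return Region(_to_polygonal(unary_union([r.geom for r in regions])))


def transpose_outline(
    outline: Outline,
    cotyledon: Outline,
    seed: int,
    max_attempts: int = 1000,
) -> Outline:
    """Rigidly translate a sector outline to a uniform random position inside a cotyledon.

    Used to build shape-matched "geometric sector" controls: the sector keeps
    its exact shape and area and only its position changes.  The translation
    target is drawn uniformly over placements of the sector's bounding box
    within the cotyledon's bounding box; a draw is accepted only if the whole
    transposed sector lies inside the cotyledon.  Deterministic given ``seed``.

    Raises
    ------
    PlacementError
        If no fully-interior placement is found in ``max_attempts`` draws
        (mirrors the exclusion of transposed sectors falling outside).
    """
    rng = np.random.default_rng(seed)
    v = outline.vertices
    minx, miny, maxx, maxy = outline.bounds
    cminx, cminy, cmaxx, cmaxy = cotyledon.bounds
    w, h = maxx - minx, maxy - miny
    cw, ch = cmaxx - cminx, cmaxy - cminy
    if w > cw or h > ch:
        raise PlacementError("sector bounding box exceeds cotyledon bounding box")
    cot_poly = cotyledon.polygon
    for _ in range(max_attempts):
        ox = rng.uniform(cminx - minx, cminx - minx + (cw - w))
        oy = rng.uniform(cminy - miny, cminy - miny + (ch - h))
        moved = v + np.array([ox, oy])
        if cot_poly.covers(Polygon(moved)):
            return Outline(moved)
    raise PlacementError(f"no interior placement found in {max_attempts} attempts")
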