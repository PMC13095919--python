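"""Spatial delineation and demographic assignment.

Labeled cluster points become area coverage through Thiessen (Voronoi)
tessellation clipped to the study boundary, cells are dissolved by composite
label into (possibly multipart) climate regions, zip-like units receive a
dasymetric total population and population-weighted centroid from a fine
population raster, and each zip is assigned to the region containing its
weighted centroid.

All coordinates are planar (km); areas are in squared coordinate units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union, voronoi_diagram
from shapely.strtree import STRtree

logger = logging.getLogger(__name__)

__all__ = [
    "PopulationRaster",
    "RegionPolygon",
    "ZipUnit",
    "CentroidResult",
    "thiessen_polygons",
    "dissolve_by_label",
    "detect_fragmented",
    "population_weighted_centroid",
    "build_zip_units",
    "assign_zip_to_region",
    "region_population",
    "region_adjacency",
    "fragment_adjacency",
]


@dataclass
class PopulationRaster:
    """Fine grid of persons-per-pixel.

    ``values[0, :]`` is the northernmost row; ``(x0, y0)`` is the lower-left
    corner. Values are non-negative person counts (floats holding integers
    under the generator's rounding policy).
    """

    x0: float
    y0: float
    cellsize: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("raster values must be finite and non-negative")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates as 2-D arrays matching ``values``."""
        xs = self.x0 + (np.arange(self.ncols) + 0.5) * self.cellsize
        ys = self.y0 + (self.nrows - np.arange(self.nrows) - 0.5) * self.cellsize
        return np.meshgrid(xs, ys)

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class RegionPolygon:
    """Dissolved geometry of one climate region.

    ``fragments`` lists the disjoint parts ordered by descending area (ties
    broken by original part index, so the "main" part is ``fragments[0]``).
    """

    region_id: str
    geometry: BaseGeometry
    fragments: list[Polygon] = field(default_factory=list)

    @property
    def area(self) -> float:
        return float(self.geometry.area)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


@dataclass
class ZipUnit:
    """Zip-like administrative polygon with dasymetric attributes."""

    zip_id: str
    polygon: Polygon
    total_population: float = 0.0
    weighted_centroid: Point | None = None
    zero_population: bool = False
    assigned_region: str | None = None


@dataclass(frozen=True)
class CentroidResult:
    point: Point
    total: float
    zero_population: bool


def thiessen_polygons(
    points: Sequence[tuple[float, float]] | np.ndarray, boundary: Polygon
) -> list[Polygon]:
    """Voronoi cells of ``points`` clipped to ``boundary``, in input order.

    Each returned cell is the locus of boundary locations nearer its
    generator than any other generator. Unbounded outer cells are closed by
    the tessellation envelope before clipping, so the result does not depend
    on the envelope size.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("points must be a non-empty (n, 2) array")
    if len(np.unique(pts, axis=0)) != len(pts):
        raise ValueError("duplicate generator coordinates")
    inside = shapely.intersects_xy(boundary, pts[:, 0], pts[:, 1])
    if not inside.all():
        raise ValueError(f"{int((~inside).sum())} generator(s) outside the boundary")

    if len(pts) == 1:
        return [Polygon(boundary.exterior, [r for r in boundary.interiors])]

    raw = voronoi_diagram(
        MultiPoint(pts.tolist()), envelope=boundary.buffer(boundary.length)
    )
    cells = list(raw.geoms)
    tree = STRtree(cells)
    out: list[Polygon | None] = [None] * len(pts)
    for i, (x, y) in enumerate(pts):
        p = Point(x, y)
        for j in tree.query(p):
            if cells[j].covers(p):
                out[i] = cells[j].intersection(boundary)
                break
        if out[i] is None:  # pragma: no cover - shapely guarantees coverage
            raise RuntimeError("generator not covered by any Voronoi cell")
    return out  # type: ignore[return-value]


def _parts(geom: BaseGeometry) -> list[Polygon]:
    if geom.is_empty:
        return []
    if geom.geom_type == "Polygon":
        return [geom]
    return [g for g in geom.geoms if g.geom_type == "Polygon"]


def dissolve_by_label(
    cells: Sequence[BaseGeometry], labels: Sequence[str]
) -> dict[str, RegionPolygon]:
    """Union same-label cells into regions with a fragment inventory."""
    if len(cells) != len(labels):
        raise ValueError("cells and labels must align")
    regions: dict[str, RegionPolygon] = {}
    for lab in sorted(set(str(x) for x in labels)):
        member = [c for c, l in zip(cells, labels) if str(l) == lab]
        geom = unary_union(member)
        parts = _parts(geom)
        order = sorted(range(len(parts)), key=lambda i: (-parts[i].area, i))
        regions[lab] = RegionPolygon(lab, geom, [parts[i] for i in order])
    return regions


def detect_fragmented(regions: Mapping[str, RegionPolygon]) -> list[str]:
    """Region ids whose dissolved geometry has more than one disjoint part."""
    return sorted(r for r, reg in regions.items() if reg.n_fragments > 1)


def population_weighted_centroid(
    polygon: BaseGeometry, raster: PopulationRaster
) -> CentroidResult:
    """Dasymetric total and population-weighted centroid of ``polygon``.

    Pixel membership is by pixel-center-in-polygon (boundary inclusive); the
    centroid is the population-mass-weighted mean of member pixel centers.
    A zero-population polygon falls back to its geometric centroid and is
    flagged.
    """
    X, Y = raster.pixel_centers()
    # bbox prefilter keeps the vectorized point test cheap on fine rasters
    minx, miny, maxx, maxy = polygon.bounds
    half = raster.cellsize  # one-pixel margin
    sel = (X >= minx - half) & (X <= maxx + half) & (Y >= miny - half) & (Y <= maxy + half)
    xs, ys, vals = X[sel], Y[sel], raster.values[sel]
    if xs.size:
        member = shapely.intersects_xy(polygon, xs, ys)
    else:
        member = np.zeros(0, dtype=bool)
    total = float(vals[member].sum())
    if total <= 0:
        logger.warning("polygon holds no population; using geometric centroid")
        return CentroidResult(polygon.centroid, 0.0, True)
    cx = float((vals[member] * xs[member]).sum() / total)
    cy = float((vals[member] * ys[member]).sum() / total)
    return CentroidResult(Point(cx, cy), total, False)


def build_zip_units(
    zip_polygons: Iterable[tuple[str, Polygon]], raster: PopulationRaster
) -> list[ZipUnit]:
    """Attach dasymetric population totals and weighted centroids to zips."""
    units = []
    for zip_id, poly in zip_polygons:
        res = population_weighted_centroid(poly, raster)
        units.append(
            ZipUnit(str(zip_id), poly, res.total, res.point, res.zero_population)
        )
    return units


def assign_zip_to_region(
    zips: Sequence[ZipUnit], regions: Mapping[str, RegionPolygon]
) -> dict[str, str]:
    """Map each zip to the region containing its population-weighted centroid.

    A centroid exactly on a shared edge goes to the lexicographically
    smallest region id; a centroid outside every region (numeric edge case)
    goes to the nearest region by boundary distance, logged.
    """
    region_ids = sorted(regions)
    mapping: dict[str, str] = {}
    for z in zips:
        pt = z.weighted_centroid if z.weighted_centroid is not None else z.polygon.centroid
        hits = [rid for rid in region_ids if regions[rid].geometry.covers(pt)]
        if hits:
            mapping[z.zip_id] = hits[0]
        else:
            nearest = min(region_ids, key=lambda rid: regions[rid].geometry.distance(pt))
            logger.warning(
                "zip %s centroid outside all regions; assigned nearest region %s",
                z.zip_id,
                nearest,
            )
            mapping[z.zip_id] = nearest
        z.assigned_region = mapping[z.zip_id]
    return mapping


def region_population(
    assignments: Mapping[str, str],
    zip_populations: Mapping[str, float],
    region_ids: Iterable[str] | None = None,
) -> dict[str, float]:
    """Sum zip populations per assigned region; empty regions report 0."""
    totals: dict[str, float] = {str(r): 0.0 for r in (region_ids or [])}
    for zip_id, rid in assignments.items():
        totals[rid] = totals.get(rid, 0.0) + float(zip_populations[zip_id])
    return totals


_TOUCH_TOL = 1e-9


def region_adjacency(regions: Mapping[str, RegionPolygon]) -> dict[str, set[str]]:
    """Rook-style adjacency between regions (shared boundary of positive length)."""
    ids = sorted(regions)
    adj: dict[str, set[str]] = {r: set() for r in ids}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            inter = regions[a].geometry.intersection(regions[b].geometry)
            if inter.length > _TOUCH_TOL:
                adj[a].add(b)
                adj[b].add(a)
    return adj


def fragment_adjacency(
    regions: Mapping[str, RegionPolygon],
) -> dict[tuple[str, int], set[str]]:
    """Adjacency of each fragment of each region to other regions."""
    ids = sorted(regions)
    adj: dict[tuple[str, int], set[str]] = {}
    for rid in ids:
        for fi, frag in enumerate(regions[rid].fragments):
            neigh = set()
            for other in ids:
                if other == rid:
                    continue
                if frag.intersection(regions[other].geometry).length > _TOUCH_TOL:
                    neigh.add(other)
            adj[(rid, fi)] = neigh
    return adj
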