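"""Human-readable region descriptors.

Each consolidated region gets a descriptor "<locations> <categories>": the
locations are the names of reference-layer polygons the region overlaps by
at least 25% of its own area, and the categories are the modal temperature
bands of its mean monthly apparent temperatures. Bands are defined in degF
with half-open [lo, hi) boundaries; the coolest band is extended below its
nominal 50 degF floor so the scale is total (regions cooler than 50 degF
are still "Coolest").
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry.base import BaseGeometry

from .spatial import RegionPolygon
from .thermal import c_to_f

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryScale",
    "DEFAULT_SCALE",
    "temp_category",
    "modal_categories",
    "location_labels",
    "build_summaries",
]


@dataclass(frozen=True)
class CategoryScale:
    """Ordered, exhaustive, disjoint temperature bands in degF.

    ``bounds`` are the interior band edges; band i covers
    [bounds[i-1], bounds[i]) with open ends below the first and above the
    last edge.
    """

    names: tuple[str, ...] = ("Coolest", "Cool", "Moderate", "Warm", "Hot", "Hottest")
    bounds: tuple[float, ...] = (60.0, 70.0, 75.0, 80.0, 85.0)

    def __post_init__(self) -> None:
        if len(self.names) != len(self.bounds) + 1:
            raise ValueError("need one more name than interior bounds")
        if list(self.bounds) != sorted(self.bounds):
            raise ValueError("bounds must be increasing")

    def order(self, name: str) -> int:
        return self.names.index(name)


DEFAULT_SCALE = CategoryScale()


def temp_category(value_f: float, scale: CategoryScale = DEFAULT_SCALE) -> str:
    """Band name for a mean monthly apparent temperature in degF."""
    if not np.isfinite(value_f):
        raise ValueError("temperature must be finite")
    # right-closed search => half-open [lo, hi) bands
    return scale.names[int(np.searchsorted(scale.bounds, value_f, side="right"))]


def modal_categories(
    categories: Sequence[str], scale: CategoryScale = DEFAULT_SCALE
) -> tuple[str, ...]:
    """Modal temperature category, or the two categories a region spans.

    One distinct category reports itself; exactly two report both; more
    than two report the two most frequent (logged). Ordering is by
    descending frequency, then by position on the scale.
    """
    if not categories:
        raise ValueError("need at least one monthly category")
    counts = Counter(categories)
    if len(counts) > 2:
        logger.info("region spans %d categories; reporting the two most frequent", len(counts))
    ranked = sorted(counts, key=lambda c: (-counts[c], scale.order(c)))
    return tuple(ranked[: min(2, len(ranked))])


def location_labels(
    region_geometry: BaseGeometry,
    reference_layer: Iterable[tuple[str, BaseGeometry]],
    threshold: float = 0.25,
) -> list[str]:
    """Reference-layer names overlapping >= ``threshold`` of the region's area.

    The denominator is the climate region's own area; names come back in
    descending overlap order. A region outside the reference layer entirely
    yields an empty list with a warning.
    """
    area = region_geometry.area
    if area <= 0:
        raise ValueError("region has no area")
    fractions = [
        (region_geometry.intersection(ref).area / area, name)
        for name, ref in reference_layer
    ]
    if all(f == 0 for f, _ in fractions):
        logger.warning("region lies outside the reference layer entirely")
    kept = [(f, name) for f, name in fractions if f >= threshold]
    return [name for _, name in sorted(kept, key=lambda t: (-t[0], t[1]))]


def build_summaries(
    regions: Mapping[str, RegionPolygon],
    region_monthly: pd.DataFrame,
    populations: Mapping[str, float],
    reference_layer: Sequence[tuple[str, BaseGeometry]],
    scale: CategoryScale = DEFAULT_SCALE,
    overlap_threshold: float = 0.25,
) -> pd.DataFrame:
    """One descriptor row per consolidated region.

    ``region_monthly`` is regions x months mean apparent temperature in
    degC. The descriptor hyphen-joins locations then categories, e.g.
    "West-Central Moderate-Warm". Rows missing a population are emitted with
    a flag rather than dropped.
    """
    rows = []
    for rid in sorted(regions):
        monthly_c = region_monthly.loc[rid].to_numpy(dtype=float)
        monthly_f = np.asarray(c_to_f(monthly_c))
        cats = modal_categories([temp_category(v, scale) for v in monthly_f], scale)
        locs = location_labels(regions[rid].geometry, reference_layer, overlap_threshold)
        missing_pop = rid not in populations
        if missing_pop:
            logger.warning("region %s has no population; row flagged", rid)
        descriptor = ("-".join(locs) + " " if locs else "") + "-".join(cats)
        rows.append(
            {
                "region_id": rid,
                "description": descriptor,
                "total_population": populations.get(rid, np.nan),
                "population_missing": missing_pop,
                "mean_at_min_c": float(monthly_c.min()),
                "mean_at_max_c": float(monthly_c.max()),
                "mean_at_min_f": float(monthly_f.min()),
                "mean_at_max_f": float(monthly_f.max()),
            }
        )
    return pd.DataFrame(rows)
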