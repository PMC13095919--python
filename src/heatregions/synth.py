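"""Synthetic study inputs: gridded apparent-temperature series with planted
region structure, zip-like polygon partitions, and fine population rasters.

The generator emulates the shape of the study inputs — a coarse reanalysis
grid (default 31 km spacing) carrying warm-season daily apparent-temperature
series, a much finer dasymetric population raster, and an administrative
partition of the study boundary — with a fully seeded, planted-truth
generative model so every downstream stage can be tested without any
external download.

Generative model for the series of cell ``c`` in planted region ``r`` on
warm-season day ``d`` (day ``d0`` opens the season of length ``L`` days)::

    AT(c, d) = a_r + s_r * sin(pi * (d - d0) / L) + b_c + eps(c, d)

with a region baseline ``a_r`` (degC), a half-sine seasonal ramp of amplitude
``s_r`` (degC), a cell offset ``b_c ~ N(0, sigma_cell^2)`` and day noise
``eps ~ N(0, sigma_day^2)``. With both sigmas zero every cell of a region
carries exactly the region profile, which is what the planted-recovery tests
exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .spatial import PopulationRaster, thiessen_polygons

__all__ = [
    "GridGeometry",
    "SeasonCalendar",
    "PlantedTruth",
    "GridSeriesSet",
    "generate_grid",
    "plant_regions",
    "default_profiles",
    "simulate_daily_series",
    "generate_zip_polygons",
    "simulate_population",
    "generate_reference_layer",
]


@dataclass(frozen=True)
class GridGeometry:
    """Regular lattice of square cells tiling a rectangle.

    Cells are numbered row-major from the south-west corner; centroids sit at
    cell centers. Coordinates are planar km.
    """

    nx: int
    ny: int
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)

    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def cell_ids(self) -> np.ndarray:
        return np.arange(self.n_cells)

    def centroids(self) -> np.ndarray:
        """(n_cells, 2) centroid coordinates, row-major from the SW corner."""
        ix = np.arange(self.n_cells) % self.nx
        iy = np.arange(self.n_cells) // self.nx
        x = self.origin[0] + (ix + 0.5) * self.spacing
        y = self.origin[1] + (iy + 0.5) * self.spacing
        return np.column_stack([x, y])

    def cell_polygon(self, cell_id: int) -> Polygon:
        ix, iy = cell_id % self.nx, cell_id // self.nx
        x0 = self.origin[0] + ix * self.spacing
        y0 = self.origin[1] + iy * self.spacing
        return box(x0, y0, x0 + self.spacing, y0 + self.spacing)

    def cell_polygons(self) -> list[Polygon]:
        return [self.cell_polygon(c) for c in range(self.n_cells)]

    def boundary(self) -> Polygon:
        x0, y0 = self.origin
        return box(x0, y0, x0 + self.nx * self.spacing, y0 + self.ny * self.spacing)

    def rook_neighbors(self, cell_id: int) -> list[int]:
        """Edge-sharing neighbors of a cell (2–4 of them)."""
        ix, iy = cell_id % self.nx, cell_id // self.nx
        out = []
        for dx, dy in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            jx, jy = ix + dx, iy + dy
            if 0 <= jx < self.nx and 0 <= jy < self.ny:
                out.append(jy * self.nx + jx)
        return sorted(out)


def generate_grid(
    nx: int, ny: int, spacing: float = 31.0, origin: tuple[float, float] = (0.0, 0.0)
) -> GridGeometry:
    """Build an ``nx`` x ``ny`` lattice of square cells of side ``spacing`` km."""
    if nx < 1 or ny < 1:
        raise ValueError("grid dimensions must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    return GridGeometry(int(nx), int(ny), float(spacing), (float(origin[0]), float(origin[1])))


def plant_regions(grid: GridGeometry, n_regions: int, seed: int) -> np.ndarray:
    """Partition the grid into ``n_regions`` rook-contiguous regions.

    Regions grow by iterative frontier expansion from seeded start cells:
    regions take turns (in label order) claiming their lowest-``cell_id``
    unlabeled rook neighbor. Labels are 1-based; identical seeds give
    identical partitions.
    """
    n = grid.n_cells
    if not 1 <= n_regions <= n:
        raise ValueError("n_regions must be in [1, n_cells]")
    rng = np.random.default_rng(seed)
    starts = rng.choice(n, size=n_regions, replace=False)
    labels = np.zeros(n, dtype=int)
    for r, c in enumerate(starts, start=1):
        labels[c] = r
    remaining = n - n_regions
    while remaining:
        progressed = False
        for r in range(1, n_regions + 1):
            frontier = [
                nb
                for c in np.flatnonzero(labels == r)
                for nb in grid.rook_neighbors(c)
                if labels[nb] == 0
            ]
            if frontier:
                labels[min(frontier)] = r
                remaining -= 1
                progressed = True
                if not remaining:
                    break
        if not progressed:  # pragma: no cover - impossible on a connected grid
            raise RuntimeError("region growing stalled")
    return labels


def default_profiles(
    n_regions: int,
    baseline_range: tuple[float, float] = (12.0, 36.0),
    amplitude_range: tuple[float, float] = (2.0, 8.0),
    seed: int = 0,
) -> dict[int, tuple[float, float]]:
    """Region profiles (baseline degC, seasonal amplitude degC).

    Baselines are evenly spread over the warm-season apparent-temperature
    span of a climatically diverse mid-latitude state (coolest mountain to
    hottest desert regions); amplitudes are drawn uniformly.
    """
    rng = np.random.default_rng(seed)
    baselines = np.linspace(*baseline_range, n_regions)
    amplitudes = rng.uniform(*amplitude_range, size=n_regions)
    return {r + 1: (float(baselines[r]), float(amplitudes[r])) for r in range(n_regions)}


@dataclass(frozen=True)
class SeasonCalendar:
    """Warm-season windows over one or more years (default May 1 – Sep 30)."""

    years: tuple[int, ...] = (2021, 2022)
    start: tuple[int, int] = (5, 1)  # (month, day)
    end: tuple[int, int] = (9, 30)

    def __post_init__(self) -> None:
        if not self.years:
            raise ValueError("calendar must cover at least one year")
        if self.start >= self.end:
            raise ValueError("season start must precede season end")

    def season_dates(self, year: int) -> pd.DatetimeIndex:
        return pd.date_range(
            pd.Timestamp(year, *self.start), pd.Timestamp(year, *self.end), freq="D"
        )

    def dates(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(
            np.concatenate([self.season_dates(y).values for y in self.years])
        )

    @property
    def season_length(self) -> int:
        return len(self.season_dates(self.years[0]))

    def day_of_season(self) -> np.ndarray:
        """0-based day index within each season, concatenated over years."""
        L = self.season_length
        return np.tile(np.arange(L), len(self.years))


@dataclass(frozen=True)
class PlantedTruth:
    """Planted generative structure: labels, profiles, noise levels, seed."""

    grid: GridGeometry
    labels: np.ndarray  # 1-based region label per cell
    profiles: dict[int, tuple[float, float]]
    sigma_cell: float = 0.0
    sigma_day: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.labels) != self.grid.n_cells:
            raise ValueError("one label per cell required")
        if self.sigma_cell < 0 or self.sigma_day < 0:
            raise ValueError("noise scales must be non-negative")
        missing = set(np.unique(self.labels)) - set(self.profiles)
        if missing:
            raise ValueError(f"profiles missing for regions {sorted(missing)}")


@dataclass
class GridSeriesSet:
    """Per-cell daily apparent-temperature series with centroids and calendar."""

    cell_ids: np.ndarray
    centroids: np.ndarray  # (n_cells, 2)
    dates: pd.DatetimeIndex
    values: np.ndarray  # (n_cells, n_days), degC
    truth: PlantedTruth | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.cell_ids), len(self.dates)):
            raise ValueError("values must be (n_cells, n_days)")

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns (cell_id, date, at_c)."""
        n_days = len(self.dates)
        return pd.DataFrame(
            {
                "cell_id": np.repeat(self.cell_ids, n_days),
                "date": np.tile(self.dates.values, self.n_cells),
                "at_c": self.values.ravel(),
            }
        )

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, centroids: np.ndarray | None = None
    ) -> "GridSeriesSet":
        wide = frame.pivot_table(index="cell_id", columns="date", values="at_c")
        if wide.isna().any().any():
            raise ValueError("incomplete series: every cell needs every date")
        cell_ids = wide.index.to_numpy()
        if centroids is None:
            centroids = np.zeros((len(cell_ids), 2))
        return cls(
            cell_ids,
            np.asarray(centroids, dtype=float),
            pd.DatetimeIndex(wide.columns),
            wide.to_numpy(),
        )


def simulate_daily_series(
    truth: PlantedTruth, calendar: SeasonCalendar | None = None
) -> GridSeriesSet:
    """Draw the planted-model daily apparent-temperature series.

    Deterministic given ``truth.seed``; with both noise scales zero every
    cell carries exactly its region's seasonal profile.
    """
    calendar = calendar or SeasonCalendar()
    dates = calendar.dates()
    d = calendar.day_of_season()
    L = calendar.season_length
    n_cells, n_days = truth.grid.n_cells, len(dates)
    seasonal = np.sin(np.pi * d / L)  # half-sine ramp over each season

    mu = np.empty((n_cells, n_days))
    for c in range(n_cells):
        a, s = truth.profiles[int(truth.labels[c])]
        mu[c] = a + s * seasonal

    rng = np.random.default_rng(truth.seed)
    b = rng.normal(0.0, truth.sigma_cell, size=n_cells) if truth.sigma_cell else np.zeros(n_cells)
    eps = (
        rng.normal(0.0, truth.sigma_day, size=(n_cells, n_days))
        if truth.sigma_day
        else np.zeros((n_cells, n_days))
    )
    values = mu + b[:, None] + eps
    return GridSeriesSet(truth.grid.cell_ids, truth.grid.centroids(), dates, values, truth)


def generate_zip_polygons(
    boundary: Polygon, n_zips: int, seed: int
) -> list[tuple[str, Polygon]]:
    """Partition ``boundary`` into ``n_zips`` Voronoi cells of seeded points.

    Zip ids are zero-padded ("Z001", ...). Identical seeds give identical
    partitions; cell areas sum to the boundary area.
    """
    if n_zips < 1:
        raise ValueError("n_zips must be >= 1")
    if n_zips == 1:
        return [("Z001", boundary)]
    rng = np.random.default_rng(seed)
    minx, miny, maxx, maxy = boundary.bounds
    pts: list[tuple[float, float]] = []
    import shapely as _shp

    while len(pts) < n_zips:
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(n_zips, 2))
        keep = _shp.intersects_xy(boundary, cand[:, 0], cand[:, 1])
        for p in cand[keep]:
            if len(pts) < n_zips:
                pts.append((float(p[0]), float(p[1])))
    cells = thiessen_polygons(pts, boundary)
    width = max(3, len(str(n_zips)))
    return [(f"Z{i + 1:0{width}d}", cell) for i, cell in enumerate(cells)]


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` by weights, exact by construction."""
    if weights.sum() <= 0:
        raise ValueError("weights must have positive sum")
    quota = weights / weights.sum() * total
    base = np.floor(quota).astype(np.int64)
    short = total - int(base.sum())
    if short:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:short]] += 1
    return base


def simulate_population(
    boundary: Polygon,
    resolution: float,
    pattern: str = "clustered",
    total: int = 1_000_000,
    seed: int = 0,
    n_clusters: int = 5,
) -> PopulationRaster:
    """Synthesize a fine population raster over the boundary's bounding box.

    Patterns: ``uniform`` (equal weight everywhere), ``point-mass`` (one
    seeded pixel holds everything), ``gradient`` (weight increasing west to
    east), ``clustered`` (seeded Gaussian population centers, emulating the
    urban concentration a dasymetric product exhibits). Pixel values are
    integers apportioned by largest remainder, so they sum to ``total``
    exactly.
    """
    if total < 0:
        raise ValueError("total population must be non-negative")
    minx, miny, maxx, maxy = boundary.bounds
    ncols = max(1, int(round((maxx - minx) / resolution)))
    nrows = max(1, int(round((maxy - miny) / resolution)))
    rng = np.random.default_rng(seed)
    xs = minx + (np.arange(ncols) + 0.5) * resolution
    ys = miny + (nrows - np.arange(nrows) - 0.5) * resolution
    X, Y = np.meshgrid(xs, ys)

    if pattern == "uniform":
        weights = np.ones((nrows, ncols))
    elif pattern == "point-mass":
        weights = np.zeros((nrows, ncols))
        weights[rng.integers(nrows), rng.integers(ncols)] = 1.0
    elif pattern == "gradient":
        weights = (X - minx) + 0.5 * resolution
    elif pattern == "clustered":
        centers = rng.uniform((minx, miny), (maxx, maxy), size=(n_clusters, 2))
        scale = 0.12 * max(maxx - minx, maxy - miny)
        weights = np.zeros((nrows, ncols))
        for cx, cy in centers:
            weights += np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * scale**2))
        weights += 1e-6  # sparse rural background
    else:
        raise ValueError(f"unknown pattern {pattern!r}")

    if pattern == "uniform" and total % (nrows * ncols) == 0:
        values = np.full((nrows, ncols), total // (nrows * ncols), dtype=np.int64)
    else:
        values = _largest_remainder(weights.ravel(), int(total)).reshape(nrows, ncols)
    return PopulationRaster(minx, miny, float(resolution), values.astype(float))


def generate_reference_layer(
    boundary: Polygon, nx: int = 3, ny: int = 3
) -> list[tuple[str, Polygon]]:
    """Tile the boundary into an ``nx`` x ``ny`` named reference layer.

    Stands in for a coarse assessment-region layer used for locational
    labels; names are compass-style for a 3x3 layout, otherwise "R<i>".
    """
    minx, miny, maxx, maxy = boundary.bounds
    xs = np.linspace(minx, maxx, nx + 1)
    ys = np.linspace(miny, maxy, ny + 1)
    compass = {
        (0, 2): "Northwest", (1, 2): "North", (2, 2): "Northeast",
        (0, 1): "West", (1, 1): "Central", (2, 1): "East",
        (0, 0): "Southwest", (1, 0): "South", (2, 0): "Southeast",
    }
    out = []
    k = 0
    for j in range(ny):
        for i in range(nx):
            k += 1
            name = compass.get((i, j), f"R{k}") if (nx, ny) == (3, 3) else f"R{k}"
            cell = box(xs[i], ys[j], xs[i + 1], ys[j + 1]).intersection(boundary)
            out.append((name, cell))
    return out
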