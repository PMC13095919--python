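"""Light-weight readers/writers for the plain-text formats the pipeline uses.

Geometry travels as GeoJSON (via :func:`shapely.geometry.mapping` /
:func:`shapely.geometry.shape`), rasters as ESRI-style ASCII grids, and all
tabular intermediates as CSV through pandas. Coordinates are treated as
already projected planar kilometres; a ``crs`` member in the GeoJSON records
the declared system but is not interpreted.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "write_geojson",
    "read_geojson",
    "write_ascii_grid",
    "read_ascii_grid",
]


def write_geojson(
    path: str | Path,
    features: Iterable[tuple[Any, BaseGeometry, Mapping[str, Any]]],
    crs: str = "planar-km",
) -> None:
    """Write ``(id, geometry, properties)`` triples as a FeatureCollection."""
    collection = {
        "type": "FeatureCollection",
        "crs": {"type": "name", "properties": {"name": crs}},
        "features": [
            {
                "type": "Feature",
                "id": fid,
                "geometry": mapping(geom),
                "properties": dict(props),
            }
            for fid, geom, props in features
        ],
    }
    Path(path).write_text(json.dumps(collection))


def read_geojson(path: str | Path) -> list[tuple[Any, BaseGeometry, dict[str, Any]]]:
    """Read a FeatureCollection back into ``(id, geometry, properties)`` triples."""
    doc = json.loads(Path(path).read_text())
    if doc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    out = []
    for feat in doc["features"]:
        out.append(
            (feat.get("id"), shape(feat["geometry"]), dict(feat.get("properties", {})))
        )
    return out


def write_ascii_grid(
    path: str | Path, values: np.ndarray, x0: float, y0: float, cellsize: float
) -> None:
    """Write a 2-D array as an ASCII grid.

    Row 0 of ``values`` is the northernmost row; ``(x0, y0)`` is the
    lower-left corner of the grid, following the ESRI header convention.
    """
    values = np.asarray(values)
    if values.ndim != 2:
        raise ValueError("raster values must be a 2-D array")
    nrows, ncols = values.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {y0!r}\n"
        f"cellsize {cellsize!r}\n"
    )
    body = "\n".join(" ".join(repr(v) for v in row) for row in values.tolist())
    Path(path).write_text(header + body + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, float, float, float]:
    """Read an ASCII grid, returning ``(values, x0, y0, cellsize)``."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in (
        "ncols",
        "nrows",
        "xllcorner",
        "yllcorner",
        "cellsize",
        "nodata_value",
    ):
        key, val = lines[i].split(maxsplit=1)
        header[key.lower()] = float(val)
        i += 1
    values = np.array([[float(v) for v in line.split()] for line in lines[i:] if line])
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: body shape does not match header")
    return values, header["xllcorner"], header["yllcorner"], header["cellsize"]
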