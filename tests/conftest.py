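"""Shared fixtures: planted grids, hierarchical scenes, merge-plan fixtures."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings
from shapely.geometry import box

from heatregions import spatial as sp
from heatregions.synth import (
    PlantedTruth,
    generate_grid,
    simulate_daily_series,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def hierarchical_truth(sigma_day: float = 0.0, seed: int = 0) -> PlantedTruth:
    """6x6 grid with 3 super-regions (vertical strips) of 2 sub-profiles each.

    Super baselines sit 10 degC apart; the two sub-profiles within a strip
    differ by 2 degC, so a "10% of profile separation" day noise is 0.2 degC.
    """
    grid = generate_grid(6, 6, 31.0)
    ix = grid.cell_ids % 6
    iy = grid.cell_ids // 6
    leaf = (ix // 2) * 2 + (iy >= 3).astype(int) + 1
    profiles = {
        s * 2 + b + 1: (12.0 + 10.0 * s + 2.0 * b, 4.0 + s)
        for s in range(3)
        for b in range(2)
    }
    return PlantedTruth(grid, leaf, profiles, 0.0, sigma_day, seed=seed)


@pytest.fixture(scope="session")
def hier_truth() -> PlantedTruth:
    return hierarchical_truth()


@pytest.fixture(scope="session")
def hier_series(hier_truth):
    return simulate_daily_series(hier_truth)


def row_of_boxes_regions() -> dict[str, sp.RegionPolygon]:
    """35 labeled unit squares in a row; region "7" has a detached part."""
    cells = [box(i, 0, i + 1, 1) for i in range(36)]
    labels = [str(i + 1) for i in range(35)] + ["7"]
    return sp.dissolve_by_label(cells, labels)


@pytest.fixture()
def regions35() -> dict[str, sp.RegionPolygon]:
    return row_of_boxes_regions()
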