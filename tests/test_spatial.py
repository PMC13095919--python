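"""Thiessen tessellation, dissolution, dasymetric centroids, zip assignment."""

import numpy as np
import pytest
import shapely
from shapely.geometry import Point, box

from heatregions import spatial as sp
from heatregions.synth import generate_zip_polygons, simulate_population


class TestThiessen:
    def test_two_symmetric_points_split_the_square_evenly(self):
        b = box(0, 0, 1, 1)
        cells = sp.thiessen_polygons([(0.25, 0.5), (0.75, 0.5)], b)
        assert cells[0].area == pytest.approx(0.5, abs=1e-12)
        assert cells[1].area == pytest.approx(0.5, abs=1e-12)
        # split runs along the perpendicular bisector x = 0.5
        assert cells[0].bounds[2] == pytest.approx(0.5)

    def test_generators_inside_their_own_cells_and_area_partition(self):
        rng = np.random.default_rng(0)
        b = box(0, 0, 10, 8)
        pts = rng.uniform((0.5, 0.5), (9.5, 7.5), (9, 2))
        cells = sp.thiessen_polygons(pts, b)
        for (x, y), cell in zip(pts, cells):
            assert cell.covers(Point(x, y))
        assert sum(c.area for c in cells) == pytest.approx(b.area, rel=1e-9)

    def test_nearest_generator_oracle(self):
        # every sample point must land in the cell of its true nearest generator
        rng = np.random.default_rng(1)
        b = box(0, 0, 1, 1)
        pts = rng.uniform(0.05, 0.95, (12, 2))
        cells = sp.thiessen_polygons(pts, b)
        gx, gy = np.meshgrid(np.linspace(0.004, 0.996, 70), np.linspace(0.004, 0.996, 70))
        sample = np.column_stack([gx.ravel(), gy.ravel()])
        nearest = ((sample[:, None, :] - pts[None]) ** 2).sum(-1).argmin(1)
        for i, cell in enumerate(cells):
            inside = shapely.contains_xy(cell, sample[:, 0], sample[:, 1])
            assert np.all(nearest[inside] == i)

    def test_duplicate_points_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            sp.thiessen_polygons([(0.5, 0.5), (0.5, 0.5)], box(0, 0, 1, 1))

    def test_point_outside_boundary_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            sp.thiessen_polygons([(2.0, 2.0)], box(0, 0, 1, 1))


class TestDissolve:
    def test_single_label_recovers_the_boundary(self):
        cells = [box(0, 0, 1, 1), box(1, 0, 2, 1)]
        regions = sp.dissolve_by_label(cells, ["A", "A"])
        assert regions["A"].geometry.equals(box(0, 0, 2, 1))
        assert regions["A"].n_fragments == 1

    def test_detached_same_label_cells_form_two_fragments(self):
        cells = [box(0, 0, 1, 1), box(1, 0, 2, 1), box(2, 0, 3, 1)]
        regions = sp.dissolve_by_label(cells, ["A", "B", "A"])
        assert regions["A"].n_fragments == 2
        assert sp.detect_fragmented(regions) == ["A"]
        # fragments pairwise disjoint, areas sum to region area
        f0, f1 = regions["A"].fragments
        assert f0.intersection(f1).area == 0.0
        assert f0.area + f1.area == pytest.approx(regions["A"].area)

    def test_dissolution_conserves_area(self, regions35):
        assert sum(r.area for r in regions35.values()) == pytest.approx(36.0, rel=1e-9)

    def test_equal_area_fragments_keep_part_order(self):
        cells = [box(0, 0, 1, 1), box(5, 0, 6, 1)]
        regions = sp.dissolve_by_label(cells, ["A", "A"])
        # tie on area: main part is the lowest original part index
        assert regions["A"].fragments[0].bounds[0] == 0.0


class TestPopulationWeightedCentroid:
    def test_uniform_raster_gives_geometric_centroid(self):
        r = simulate_population(box(0, 0, 10, 10), 0.5, "uniform", 40_000, seed=0)
        poly = box(2, 2, 8, 8)
        res = sp.population_weighted_centroid(poly, r)
        assert res.point.x == pytest.approx(5.0, abs=1e-9)
        assert res.point.y == pytest.approx(5.0, abs=1e-9)
        assert not res.zero_population

    def test_single_populated_pixel(self):
        values = np.zeros((4, 4))
        values[1, 2] = 77.0
        r = sp.PopulationRaster(0, 0, 1.0, values)
        res = sp.population_weighted_centroid(box(0, 0, 4, 4), r)
        assert (res.point.x, res.point.y) == (2.5, 2.5)
        assert res.total == 77.0

    def test_two_pixel_weighted_mean(self):
        # populations 1 and 3 with centers at x=0 and x=4 -> centroid x = 3
        r = sp.PopulationRaster(-2.0, -2.0, 4.0, np.array([[1.0, 3.0]]))
        X, _ = r.pixel_centers()
        assert X.tolist() == [[0.0, 4.0]]
        res = sp.population_weighted_centroid(box(-2, -2, 6, 2), r)
        assert res.point.x == pytest.approx(3.0)
        assert res.total == 4.0

    def test_zero_population_falls_back_to_geometric_centroid(self):
        r = sp.PopulationRaster(0, 0, 1.0, np.zeros((3, 3)))
        res = sp.population_weighted_centroid(box(0, 0, 3, 3), r)
        assert res.zero_population
        assert (res.point.x, res.point.y) == (1.5, 1.5)

    def test_centroid_inside_convex_polygon(self):
        r = simulate_population(box(0, 0, 10, 10), 0.25, "clustered", 50_000, seed=3)
        poly = Point(5, 5).buffer(3.0)
        res = sp.population_weighted_centroid(poly, r)
        assert poly.covers(res.point)


class TestAssignment:
    @staticmethod
    def _two_regions():
        cells = [box(0, 0, 1, 1), box(1, 0, 2, 1)]
        return sp.dissolve_by_label(cells, ["L", "R"])

    def test_interior_centroid_assigned_to_containing_region(self):
        regions = self._two_regions()
        z = sp.ZipUnit("Z1", box(0.2, 0.2, 0.6, 0.6), 10, Point(0.4, 0.4))
        assert sp.assign_zip_to_region([z], regions) == {"Z1": "L"}

    def test_shared_edge_breaks_to_smallest_region_id(self):
        regions = self._two_regions()
        z = sp.ZipUnit("Z1", box(0.8, 0.2, 1.2, 0.6), 10, Point(1.0, 0.4))
        assert sp.assign_zip_to_region([z], regions)["Z1"] == "L"

    def test_outside_centroid_goes_to_nearest_region(self):
        regions = self._two_regions()
        z = sp.ZipUnit("Z1", box(1.5, 0, 2, 0.5), 10, Point(2.5, 0.5))
        assert sp.assign_zip_to_region([z], regions)["Z1"] == "R"

    def test_every_zip_assigned_and_population_conserved(self):
        b = box(0, 0, 20, 20)
        raster = simulate_population(b, 0.4, "clustered", 333_333, seed=4)
        zips = sp.build_zip_units(generate_zip_polygons(b, 30, seed=5), raster)
        rng = np.random.default_rng(6)
        regions = sp.dissolve_by_label(
            sp.thiessen_polygons(rng.uniform(1, 19, (8, 2)), b),
            [str(i % 4) for i in range(8)],
        )
        assignments = sp.assign_zip_to_region(zips, regions)
        assert len(assignments) == 30
        pops = sp.region_population(
            assignments, {z.zip_id: z.total_population for z in zips}, regions.keys()
        )
        assert sum(pops.values()) == raster.total  # exact conservation

    def test_empty_region_reports_zero(self):
        pops = sp.region_population({"Z1": "A"}, {"Z1": 5.0}, ["A", "B"])
        assert pops == {"A": 5.0, "B": 0.0}


class TestAdjacency:
    def test_rook_adjacency_and_fragment_adjacency(self):
        cells = [box(0, 0, 1, 1), box(1, 0, 2, 1), box(2, 0, 3, 1), box(0, 1, 1, 2)]
        regions = sp.dissolve_by_label(cells, ["A", "B", "A", "C"])
        adj = sp.region_adjacency(regions)
        assert adj["B"] == {"A"}
        assert adj["C"] == {"A"}
        fadj = sp.fragment_adjacency(regions)
        # main fragment of A touches B and C; detached fragment only B
        assert fadj[("A", 0)] == {"B", "C"}
        assert fadj[("A", 1)] == {"B"}
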