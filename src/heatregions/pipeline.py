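"""End-to-end orchestration of the regionalization stages.

``run_pipeline`` wires the stages together on a simulated scene (or on
user-supplied series), writes every intermediate artifact to the output
directory, and logs seeds, vote tallies and merge evidence. A rerun with
the same config and seed is bit-identical for the exact stages and
numerically identical for the floating ones.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import consolidate as cons
from . import describe, spatial, synth, thermal
from .cluster import ClusterLabeling, two_stage_cluster
from .config import PipelineConfig
from .io import write_ascii_grid, write_geojson

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "simulate_scene"]

_SEED_MOD = 2**31
# fixed per-stage offsets from the master seed (stage-level reproducibility)
_OFF_TRUTH, _OFF_SERIES, _OFF_ZIPS, _OFF_POP, _OFF_CLUSTER = 11, 23, 37, 53, 71


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class Scene:
    """A simulated study scene: series, zips, population, reference layer."""

    grid: synth.GridGeometry
    truth: synth.PlantedTruth
    series: synth.GridSeriesSet
    zip_polygons: list
    raster: spatial.PopulationRaster
    reference_layer: list


@dataclass
class PipelineResult:
    scene: Scene
    labeling: ClusterLabeling
    initial_regions: dict
    zips: list
    initial_populations: dict
    tests: dict
    eligible: set
    plan: cons.MergePlan
    regions: dict
    assignments: dict
    populations: dict
    region_monthly: pd.DataFrame
    summaries: pd.DataFrame
    out_dir: Path | None = None
    timings: dict = field(default_factory=dict)


def simulate_scene(config: PipelineConfig) -> Scene:
    """Generate the synthetic study inputs for one seeded run."""
    sim = config.simulation
    seed = int(config.seed) % _SEED_MOD
    grid = synth.generate_grid(sim.nx, sim.ny, sim.spacing_km)
    labels = synth.plant_regions(grid, sim.n_regions, (seed + _OFF_TRUTH) % _SEED_MOD)
    profiles = synth.default_profiles(
        sim.n_regions, sim.baseline_range, sim.amplitude_range, seed=(seed + _OFF_TRUTH) % _SEED_MOD
    )
    truth = synth.PlantedTruth(
        grid, labels, profiles, sim.sigma_cell, sim.sigma_day, (seed + _OFF_SERIES) % _SEED_MOD
    )
    calendar = synth.SeasonCalendar(config.years, config.season_start, config.season_end)
    series = synth.simulate_daily_series(truth, calendar)
    boundary = grid.boundary()
    zips = synth.generate_zip_polygons(boundary, sim.n_zips, (seed + _OFF_ZIPS) % _SEED_MOD)
    raster = synth.simulate_population(
        boundary,
        sim.spacing_km / sim.raster_refinement,
        sim.population_pattern,
        sim.total_population,
        (seed + _OFF_POP) % _SEED_MOD,
    )
    reference = synth.generate_reference_layer(boundary, sim.reference_nx, sim.reference_ny)
    return Scene(grid, truth, series, zips, raster, reference)


def _write_scene(scene: Scene, out: Path) -> None:
    scene.series.to_frame().to_csv(out / "series.csv", index=False)
    write_geojson(
        out / "zips.geojson", [(zid, poly, {"zip_id": zid}) for zid, poly in scene.zip_polygons]
    )
    write_geojson(
        out / "reference_layer.geojson",
        [(name, poly, {"name": name}) for name, poly in scene.reference_layer],
    )
    r = scene.raster
    write_ascii_grid(out / "population.asc", r.values, r.x0, r.y0, r.cellsize)
    pd.DataFrame(
        {"cell_id": scene.grid.cell_ids, "true_region": scene.truth.labels}
    ).to_csv(out / "planted_truth.csv", index=False)


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None, scene: Scene | None = None
) -> PipelineResult:
    """Run simulate → cluster → delineate → assign → consolidate → describe.

    Every intermediate is written under ``out_dir`` (omit to skip writing).
    Raises :class:`StageError` tagged with the failing stage; artifacts
    produced before the failure are left in place.
    """
    config.validate()
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def _stage(name):
        logger.info("stage: %s", name)
        timings[name] = time.perf_counter()
        return name

    def _done(name):
        timings[name] = time.perf_counter() - timings[name]

    try:
        name = _stage("simulate")
        if scene is None:
            scene = simulate_scene(config)
        if out:
            config.to_yaml(out / "resolved_config.yaml")
            _write_scene(scene, out)
        _done(name)
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    try:
        name = _stage("cluster")
        seed = (int(config.seed) + _OFF_CLUSTER) % _SEED_MOD
        labeling = two_stage_cluster(
            scene.series.values,
            cell_ids=scene.series.cell_ids,
            stage1_range=config.stage1_range,
            stage2_range=config.stage2_range,
            retention_threshold=config.retention_threshold,
            n_starts=config.n_starts,
            null_reps=config.null_reps,
            seed=seed,
            indices=config.indices,
        )
        logger.info(
            "stage-1 k=%d votes=%s; stage-2 k per cluster: %s",
            labeling.stage1_k,
            labeling.stage1_votes,
            labeling.stage2_k,
        )
        if out:
            labeling.frame.to_csv(out / "labeling.csv", index=False)
            labeling.pca_summary.to_csv(out / "pca_summary.csv", index=False)
            votes = [{"stage": "1", "cluster": "", **labeling.stage1_votes}] + [
                {"stage": "2", "cluster": c, **v} for c, v in labeling.stage2_votes.items()
            ]
            pd.DataFrame(votes).to_csv(out / "vote_tally.csv", index=False)
        _done(name)
    except Exception as exc:  # noqa: BLE001
        raise StageError("cluster", exc) from exc

    try:
        name = _stage("delineate")
        boundary = scene.grid.boundary()
        cells = spatial.thiessen_polygons(scene.series.centroids, boundary)
        initial_regions = spatial.dissolve_by_label(cells, labeling.composite)
        if out:
            write_geojson(
                out / "initial_regions.geojson",
                [
                    (rid, reg.geometry, {"region_id": rid, "n_fragments": reg.n_fragments})
                    for rid, reg in initial_regions.items()
                ],
            )
        _done(name)
    except Exception as exc:  # noqa: BLE001
        raise StageError("delineate", exc) from exc

    try:
        name = _stage("assign")
        zips = spatial.build_zip_units(scene.zip_polygons, scene.raster)
        assignments0 = spatial.assign_zip_to_region(zips, initial_regions)
        zip_pops = {z.zip_id: z.total_population for z in zips}
        initial_populations = spatial.region_population(
            assignments0, zip_pops, initial_regions.keys()
        )
        if out:
            pd.DataFrame(
                [
                    {
                        "zip_id": z.zip_id,
                        "population": z.total_population,
                        "centroid_x": z.weighted_centroid.x,
                        "centroid_y": z.weighted_centroid.y,
                        "region": assignments0[z.zip_id],
                    }
                    for z in zips
                ]
            ).to_csv(out / "zip_assignments.csv", index=False)
        _done(name)
    except Exception as exc:  # noqa: BLE001
        raise StageError("assign", exc) from exc

    try:
        name = _stage("consolidate")
        region_monthly0 = thermal.region_monthly_means(
            scene.series.to_frame(),
            dict(zip(scene.series.cell_ids, labeling.composite)),
        )
        tests = cons.pairwise_region_tests(region_monthly0, alpha=config.alpha)
        fragmented = spatial.detect_fragmented(initial_regions)
        eligible = cons.merge_eligibility(
            initial_populations,
            fragmented,
            threshold=config.population_threshold,
            percentile=config.population_percentile,
            rule=config.eligibility_rule,
        )
        plan = cons.propose_merges(
            eligible, tests, initial_regions, initial_populations, alpha=config.alpha
        )
        logger.info(
            "fragmented=%s eligible=%s directives=%d unmerged=%s",
            fragmented,
            sorted(eligible),
            len(plan.directives),
            plan.unmerged,
        )
        regions, assignments = cons.apply_merges(initial_regions, plan, zips)
        populations = spatial.region_population(assignments, zip_pops, regions.keys())
        if out:
            cons.pair_test_table(tests).to_csv(out / "pair_tests.csv", index=False)
            plan.to_frame().to_csv(out / "merge_plan.csv", index=False)
            write_geojson(
                out / "regions.geojson",
                [
                    (
                        rid,
                        reg.geometry,
                        {
                            "region_id": rid,
                            "population": populations[rid],
                            "n_fragments": reg.n_fragments,
                        },
                    )
                    for rid, reg in regions.items()
                ],
            )
        _done(name)
    except Exception as exc:  # noqa: BLE001
        raise StageError("consolidate", exc) from exc

    try:
        name = _stage("describe")
        # cell -> final region: merged sources inherit their directive targets
        relabel = {d.source: d.target for d in plan.directives if d.fragment_index is None}
        cell_final = []
        cents = scene.series.centroids
        for i, comp in enumerate(labeling.composite):
            if comp in regions:
                cell_final.append(comp)
            elif comp in relabel:
                cell_final.append(relabel[comp])
            else:
                # fragment-split source: locate the cell geometrically
                from shapely.geometry import Point

                pt = Point(cents[i])
                host = [r for r, reg in sorted(regions.items()) if reg.geometry.covers(pt)]
                cell_final.append(
                    host[0]
                    if host
                    else min(regions, key=lambda r: regions[r].geometry.distance(pt))
                )
        region_monthly = thermal.region_monthly_means(
            scene.series.to_frame(), dict(zip(scene.series.cell_ids, cell_final))
        )
        summaries = describe.build_summaries(
            regions,
            region_monthly,
            populations,
            scene.reference_layer,
            overlap_threshold=config.overlap_threshold,
        )
        if out:
            summaries.to_csv(out / "region_summaries.csv", index=False)
            pd.DataFrame(
                {"cell_id": scene.series.cell_ids, "final_region": cell_final}
            ).to_csv(out / "final_labeling.csv", index=False)
        _done(name)
    except Exception as exc:  # noqa: BLE001
        raise StageError("describe", exc) from exc

    return PipelineResult(
        scene,
        labeling,
        initial_regions,
        zips,
        initial_populations,
        tests,
        eligible,
        plan,
        regions,
        assignments,
        populations,
        region_monthly,
        summaries,
        out,
        timings,
    )
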