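"""Pipeline configuration: every constant of the procedure in one place.

Defaults hold the method's canonical settings — May–September warm seasons
over two years, Kaiser retention at 1.0, stage-1 k in 10..20 and stage-2 k
in 1..10, alpha = 0.1 for the pair tests, an 11,000-person eligibility
threshold, and the 25% locational-overlap rule — none of which is hard-coded
elsewhere. Configs load from / dump to YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class SimulationConfig:
    """Synthetic-scene settings (the generator's study conditions)."""

    nx: int = 16
    ny: int = 12
    spacing_km: float = 31.0
    n_regions: int = 12
    sigma_cell: float = 0.5
    sigma_day: float = 1.5
    baseline_range: tuple[float, float] = (12.0, 36.0)
    amplitude_range: tuple[float, float] = (2.0, 8.0)
    n_zips: int = 120
    population_pattern: str = "clustered"
    total_population: int = 1_000_000
    raster_refinement: int = 100  # population pixels per climate-cell side
    reference_nx: int = 3
    reference_ny: int = 3


@dataclass
class PipelineConfig:
    season_start: tuple[int, int] = (5, 1)  # (month, day): May 1
    season_end: tuple[int, int] = (9, 30)  # Sep 30
    years: tuple[int, ...] = (2021, 2022)
    at_variant: str = "dewpoint"
    retention_threshold: float = 1.0
    stage1_range: tuple[int, int] = (10, 20)
    stage2_range: tuple[int, int] = (1, 10)
    indices: tuple[str, ...] = (
        "silhouette",
        "calinski_harabasz",
        "davies_bouldin",
        "dunn",
        "gap",
    )
    n_starts: int = 25
    null_reps: int = 50
    alpha: float = 0.1
    population_threshold: float | None = 11_000.0
    population_percentile: float | None = None
    eligibility_rule: str = "conjunctive"
    overlap_threshold: float = 0.25
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if not self.years:
            raise ConfigError("at least one study year is required")
        if self.season_start >= self.season_end:
            raise ConfigError("season start must precede season end")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        for name, (lo, hi) in (
            ("stage1_range", self.stage1_range),
            ("stage2_range", self.stage2_range),
        ):
            if lo < 1 or hi < lo:
                raise ConfigError(f"{name} must be a non-empty 1-based range")
        if self.retention_threshold < 0:
            raise ConfigError("retention threshold must be non-negative")
        if self.population_threshold is None and self.population_percentile is None:
            raise ConfigError("need a population threshold or percentile")
        if self.population_threshold is not None and self.population_threshold < 0:
            raise ConfigError("population threshold must be non-negative")
        if not (0 <= self.overlap_threshold <= 1):
            raise ConfigError("overlap threshold must lie in [0, 1]")
        if not self.indices:
            raise ConfigError("at least one validity index is required")
        sim = self.simulation
        if sim.nx < 1 or sim.ny < 1 or sim.spacing_km <= 0:
            raise ConfigError("simulation grid dimensions must be positive")
        if not 1 <= sim.n_regions <= sim.nx * sim.ny:
            raise ConfigError("n_regions must be in [1, n_cells]")
        if sim.sigma_cell < 0 or sim.sigma_day < 0:
            raise ConfigError("noise scales must be non-negative")
        if sim.total_population < 0:
            raise ConfigError("total population must be non-negative")

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        doc = dict(doc)
        sim = doc.pop("simulation", {})
        known_sim = {f for f in SimulationConfig.__dataclass_fields__}
        known = {f for f in cls.__dataclass_fields__} - {"simulation"}
        bad = (set(doc) - known) | (set(sim) - known_sim)
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")

        def _tup(v):
            return tuple(v) if isinstance(v, list) else v

        doc = {k: _tup(v) for k, v in doc.items()}
        sim = {k: _tup(v) for k, v in sim.items()}
        cfg = cls(**doc, simulation=SimulationConfig(**sim))
        cfg.validate()
        return cfg
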