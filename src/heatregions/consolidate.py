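"""Statistically gated consolidation of fragmented, low-population regions.

Candidate regions (fragmented and below a population threshold) are merged
into a nearby region only when an exact Wilcoxon signed-rank test on the
paired mean monthly apparent temperatures cannot distinguish the two at the
chosen alpha (default 0.1) — i.e. a merge requires the *absence* of a
significant monthly-temperature difference. Among admissible partners the
one with the smallest mean absolute monthly difference wins; the disjoint
fragments of a region may be sent to different targets.

The exact test enumerates the full sign-pattern null distribution of the
signed-rank statistic (zeros dropped, midranks for tied magnitudes); with
five paired months the smallest attainable two-sided p is 2/32 = 0.0625, so
no five-month pair can be significant below alpha = 0.0625.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from shapely.ops import unary_union

from .spatial import (
    RegionPolygon,
    ZipUnit,
    assign_zip_to_region,
    fragment_adjacency,
    region_adjacency,
)

logger = logging.getLogger(__name__)

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank_exact",
    "PairTest",
    "pairwise_region_tests",
    "merge_eligibility",
    "MergeDirective",
    "MergePlan",
    "propose_merges",
    "apply_merges",
]

_EXACT_LIMIT = 20  # full enumeration above this would exceed 2^20 sign patterns


@dataclass(frozen=True)
class WilcoxonResult:
    w_plus: float
    p_two_sided: float
    n_nonzero: int
    method: str  # "exact" | "normal" | "degenerate"


def _exact_distribution(ranks2: np.ndarray) -> np.ndarray:
    """Counts of 2*W+ over all sign patterns, by convolution over ranks.

    ``ranks2`` are doubled ranks (integers even with midranks). Entry w of
    the result counts sign patterns with doubled statistic w; the total is
    2**m.
    """
    counts = np.zeros(int(ranks2.sum()) + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: len(counts) - r]
        counts += shifted
    return counts


def wilcoxon_signed_rank_exact(
    diffs: Sequence[float] | np.ndarray,
    zero_policy: str = "drop",
    tie_policy: str = "midrank",
) -> WilcoxonResult:
    """Exact two-sided Wilcoxon signed-rank test on paired differences.

    Zeros are dropped before ranking and tied magnitudes receive midranks
    (the common exact-test convention). For m <= 20 nonzero differences the
    two-sided p doubles the smaller tail of the fully enumerated null,
    capped at 1; larger m falls back to the tie-corrected normal
    approximation with continuity correction, logged. All-zero input is
    degenerate: p = 1 with a warning.
    """
    if zero_policy != "drop":
        raise ValueError("only the 'drop' zero policy is implemented")
    if tie_policy != "midrank":
        raise ValueError("only the 'midrank' tie policy is implemented")
    d = np.asarray(diffs, dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise ValueError("diffs must be a non-empty 1-D sequence")
    nz = d[d != 0]
    m = len(nz)
    if m == 0:
        warnings.warn("all differences are zero; degenerate test, p = 1", stacklevel=2)
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")
    ranks = rankdata(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())

    if m <= _EXACT_LIMIT:
        ranks2 = np.rint(2 * ranks).astype(int)
        counts = _exact_distribution(ranks2)
        total = counts.sum()
        w2 = int(round(2 * w_plus))
        p_ge = counts[w2:].sum() / total
        p_le = counts[: w2 + 1].sum() / total
        p = min(1.0, 2.0 * min(p_ge, p_le))
        return WilcoxonResult(w_plus, float(p), m, "exact")

    logger.info("m=%d > %d; using normal approximation", m, _EXACT_LIMIT)
    mean = m * (m + 1) / 4.0
    _, t_counts = np.unique(ranks, return_counts=True)
    var = m * (m + 1) * (2 * m + 1) / 24.0 - (t_counts**3 - t_counts).sum() / 48.0
    delta = w_plus - mean
    z = (delta - 0.5 * np.sign(delta)) / np.sqrt(var)
    p = min(1.0, 2.0 * norm.sf(abs(z)))
    return WilcoxonResult(w_plus, float(p), m, "normal")


@dataclass(frozen=True)
class PairTest:
    region_a: str
    region_b: str
    monthly_diffs: np.ndarray  # signed degC, a - b, one per month
    w_plus: float
    p_two_sided: float
    significant: bool

    @property
    def abs_diffs(self) -> np.ndarray:
        return np.abs(self.monthly_diffs)

    @property
    def mean_abs_diff(self) -> float:
        return float(self.abs_diffs.mean())


def pairwise_region_tests(
    region_monthly: pd.DataFrame,
    pairs: Iterable[tuple[str, str]] | None = None,
    alpha: float = 0.1,
) -> dict[frozenset, PairTest]:
    """Exact Wilcoxon tests on region-pair mean monthly temperatures.

    ``region_monthly`` is regions x months (degC). Pairs default to all
    combinations; a pair is flagged significant iff p < alpha. Month sets
    must be identical (guaranteed by the shared frame; NaN entries raise).
    """
    if region_monthly.isna().any().any():
        raise ValueError("region-monthly table has missing months")
    ids = [str(r) for r in region_monthly.index]
    if pairs is None:
        pairs = itertools.combinations(ids, 2)
    out: dict[frozenset, PairTest] = {}
    for a, b in pairs:
        if a not in ids or b not in ids:
            raise ValueError(f"unknown region in pair ({a}, {b})")
        diffs = region_monthly.loc[a].to_numpy() - region_monthly.loc[b].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = wilcoxon_signed_rank_exact(diffs)
        out[frozenset((a, b))] = PairTest(
            a, b, diffs, res.w_plus, res.p_two_sided, res.p_two_sided < alpha
        )
    return out


def pair_test_table(tests: Mapping[frozenset, PairTest]) -> pd.DataFrame:
    """Flat table of pair tests with p rounded to 2 decimals for display."""
    rows = []
    for t in tests.values():
        row = {"region_a": t.region_a, "region_b": t.region_b}
        row.update({f"abs_diff_{i + 1}": v for i, v in enumerate(t.abs_diffs)})
        row.update(
            {
                "w_plus": t.w_plus,
                "p_value": round(t.p_two_sided, 2),
                "significant": t.significant,
            }
        )
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["region_a", "region_b"]).reset_index(drop=True)


def merge_eligibility(
    populations: Mapping[str, float],
    fragmented: Iterable[str],
    threshold: float | None = 11_000,
    percentile: float | None = None,
    rule: str = "conjunctive",
) -> set[str]:
    """Regions eligible for consolidation.

    Default rule: fragmented AND population strictly below the threshold
    ("fewer than"). ``percentile`` resolves the threshold as that percentile
    of all region populations (linear interpolation); the disjunctive rule
    admits regions that are fragmented OR small.
    """
    if rule not in ("conjunctive", "disjunctive"):
        raise ValueError("rule must be 'conjunctive' or 'disjunctive'")
    if percentile is not None:
        threshold = float(np.percentile(list(populations.values()), percentile))
    if threshold is None:
        raise ValueError("either threshold or percentile is required")
    frag = {str(f) for f in fragmented}
    small = {r for r, p in populations.items() if p < threshold}
    return (frag & small) if rule == "conjunctive" else (frag | small)


@dataclass(frozen=True)
class MergeDirective:
    source: str
    target: str
    fragment_index: int | None = None  # None = whole region
    p_value: float | None = None
    mean_abs_diff: float | None = None
    source_population: float | None = None
    target_population: float | None = None
    adjacent: bool = True

    @property
    def source_key(self) -> tuple[str, int | None]:
        return (self.source, self.fragment_index)


@dataclass
class MergePlan:
    directives: list[MergeDirective] = field(default_factory=list)
    unmerged: list[str] = field(default_factory=list)

    def validate(self) -> None:
        sources = {d.source for d in self.directives}
        targets = {d.target for d in self.directives}
        if sources & targets:
            raise ValueError(f"cyclic directives: {sorted(sources & targets)}")
        keys = [d.source_key for d in self.directives]
        if len(keys) != len(set(keys)):
            raise ValueError("a source region/fragment appears more than once")
        whole = {d.source for d in self.directives if d.fragment_index is None}
        partial = {d.source for d in self.directives if d.fragment_index is not None}
        if whole & partial:
            raise ValueError("region merged both whole and by fragment")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "source": d.source,
                    "fragment": "whole" if d.fragment_index is None else d.fragment_index,
                    "target": d.target,
                    "p_value": d.p_value,
                    "mean_abs_diff": d.mean_abs_diff,
                    "source_population": d.source_population,
                    "target_population": d.target_population,
                }
                for d in self.directives
            ]
        )


def _pick_target(
    candidates: set[str],
    source: str,
    tests: Mapping[frozenset, PairTest],
    alpha: float,
    covariate: Mapping[str, float] | None,
    tau: float | None,
) -> tuple[str, PairTest] | None:
    admissible = []
    for cand in sorted(candidates):
        t = tests.get(frozenset((source, cand)))
        if t is None or t.p_two_sided < alpha:
            continue
        if covariate is not None and tau is not None:
            if abs(covariate[source] - covariate[cand]) > tau:
                continue
        admissible.append((t.mean_abs_diff, cand, t))
    if not admissible:
        return None
    _, cand, t = min(admissible, key=lambda x: (x[0], x[1]))
    return cand, t


def propose_merges(
    eligible: Iterable[str],
    tests: Mapping[frozenset, PairTest],
    regions: Mapping[str, RegionPolygon],
    populations: Mapping[str, float] | None = None,
    alpha: float = 0.1,
    covariate: Mapping[str, float] | None = None,
    tau: float | None = None,
) -> MergePlan:
    """Build a merge plan for the eligible regions.

    For a single-part region the candidate partners are its adjacent
    regions; for a fragmented region each fragment consults the regions its
    own part touches, so fragments may be routed to different targets (as
    when the main body of a region joins one neighbor while an isolated
    cluster joins another). Partners must be non-significant at ``alpha``
    and, when an elevation-style covariate and tolerance are given, within
    ``tau`` of the source. Candidates are ranked by smallest mean absolute
    monthly difference. Other eligible regions are never targets, keeping
    the plan acyclic. Eligible regions with no admissible partner are left
    unmerged and flagged for manual review.
    """
    eligible = {str(e) for e in eligible}
    adj = region_adjacency(regions)
    frag_adj = fragment_adjacency(regions)
    populations = populations or {}
    plan = MergePlan()
    for src in sorted(eligible):
        reg = regions[src]
        if reg.n_fragments <= 1:
            choice = _pick_target(adj[src] - eligible, src, tests, alpha, covariate, tau)
            if choice is None:
                logger.warning("no admissible partner for region %s; left unmerged", src)
                plan.unmerged.append(src)
                continue
            cand, t = choice
            plan.directives.append(
                MergeDirective(
                    src, cand, None, t.p_two_sided, t.mean_abs_diff,
                    populations.get(src), populations.get(cand),
                )
            )
        else:
            picks: list[tuple[int, str, PairTest]] = []
            for fi in range(reg.n_fragments):
                choice = _pick_target(
                    frag_adj[(src, fi)] - eligible, src, tests, alpha, covariate, tau
                )
                if choice is not None:
                    picks.append((fi, *choice))
            if not picks:
                logger.warning("no admissible partner for region %s; left unmerged", src)
                plan.unmerged.append(src)
                continue
            if len(picks) == reg.n_fragments and len({c for _, c, _ in picks}) == 1:
                _, cand, t = picks[0]
                plan.directives.append(
                    MergeDirective(
                        src, cand, None, t.p_two_sided, t.mean_abs_diff,
                        populations.get(src), populations.get(cand),
                    )
                )
            else:
                for fi, cand, t in picks:
                    plan.directives.append(
                        MergeDirective(
                            src, cand, fi, t.p_two_sided, t.mean_abs_diff,
                            populations.get(src), populations.get(cand),
                        )
                    )
    plan.validate()
    return plan


def apply_merges(
    regions: Mapping[str, RegionPolygon],
    plan: MergePlan,
    zips: Sequence[ZipUnit] | None = None,
) -> tuple[dict[str, RegionPolygon], dict[str, str] | None]:
    """Apply a merge plan to region geometries (and re-assign affected zips).

    Source geometries (whole regions, or named fragments) are unioned into
    their targets; a source whose parts are all given away disappears, so
    the distinct-region count drops by the number of fully absorbed sources.
    Applying a plan twice equals applying it once: directives whose source
    no longer exists are skipped. Zips previously assigned to a touched
    region are re-assigned against the consolidated geometry, so every zip
    remains assigned to exactly one region and populations are conserved.
    """
    plan.validate()
    new: dict[str, RegionPolygon] = {
        rid: RegionPolygon(rid, reg.geometry, list(reg.fragments))
        for rid, reg in regions.items()
    }
    # fragment indices in a plan name parts of the source's ORIGINAL inventory
    original_fragments = {rid: list(reg.fragments) for rid, reg in regions.items()}
    moved_fragments: dict[str, set[int]] = {}
    for d in plan.directives:
        if d.source not in new:
            continue  # already absorbed (idempotent re-application)
        if d.target not in new:
            raise ValueError(f"merge target {d.target} does not exist")
        if d.fragment_index is None:
            moved = new[d.source].geometry
            del new[d.source]
        else:
            frags = original_fragments[d.source]
            if d.fragment_index >= len(frags):
                # inventory shorter than the plan implies: directive was
                # already applied in an earlier pass
                logger.info(
                    "region %s has no fragment %d; treating directive as applied",
                    d.source,
                    d.fragment_index,
                )
                continue
            moved = frags[d.fragment_index]
            if new[d.target].geometry.covers(moved):
                continue  # already merged (idempotent re-application)
            taken = moved_fragments.setdefault(d.source, set())
            taken.add(d.fragment_index)
            remaining = [f for i, f in enumerate(frags) if i not in taken]
            if remaining:
                new[d.source] = RegionPolygon(
                    d.source, unary_union(remaining), remaining
                )
            else:
                del new[d.source]
        tgt = new[d.target]
        merged = unary_union([tgt.geometry, moved])
        parts = [merged] if merged.geom_type == "Polygon" else list(merged.geoms)
        order = sorted(range(len(parts)), key=lambda i: (-parts[i].area, i))
        new[d.target] = RegionPolygon(d.target, merged, [parts[i] for i in order])

    assignments = None
    if zips is not None:
        touched = {d.source for d in plan.directives} | {d.target for d in plan.directives}
        assignments = {}
        stale = [z for z in zips if z.assigned_region in touched or z.assigned_region is None]
        kept = {z.zip_id: z.assigned_region for z in zips if z not in stale}
        assignments.update(kept)  # type: ignore[arg-type]
        if stale:
            assignments.update(assign_zip_to_region(stale, new))
    return new, assignments
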