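"""Cluster-validity indices and the voted selection of k.

The selection emulates a many-index plurality vote: each index nominates its
optimal k over the candidate range and the plurality winner is chosen
(ties break to the smallest k). The default ensemble is silhouette,
Calinski-Harabasz, Davies-Bouldin, Dunn, and the gap statistic; the set is
config-extensible. When the range includes k = 1 ("no substructure"), that
decision is delegated to the gap statistic with uniform reference nulls,
since partition indices are undefined for a single cluster.

Degenerate-case conventions (needed on noise-free planted data, where whole
clusters can be coincident points): a singleton's silhouette is 0, as is a
point whose within- and between-distances both vanish; an unbounded Dunn
ratio is capped at 1e6; a non-finite Calinski-Harabasz or Davies-Bouldin
value is treated as worst-possible for the vote.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist
from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

from .cluster import kmeans

logger = logging.getLogger(__name__)

__all__ = [
    "silhouette",
    "dunn_index",
    "validity_indices",
    "gap_statistic",
    "GapResult",
    "SelectKResult",
    "select_k",
    "DEFAULT_INDICES",
]

DEFAULT_INDICES = ("silhouette", "calinski_harabasz", "davies_bouldin", "dunn", "gap")
_DUNN_CAP = 1.0e6


def silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette width; singletons (and 0/0 cases) contribute 0."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least two clusters")
    D = cdist(X, X)
    s = np.zeros(len(X))
    for i in range(len(X)):
        own = labels == labels[i]
        if own.sum() == 1:
            continue  # singleton convention: 0
        a = D[i, own].sum() / (own.sum() - 1)
        b = min(D[i, labels == c].mean() for c in uniq if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(s.mean())


def dunn_index(X: np.ndarray, labels: np.ndarray) -> float:
    """Min between-cluster distance over max cluster diameter, capped at 1e6."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("Dunn index needs at least two clusters")
    max_diam = 0.0
    for c in uniq:
        pts = X[labels == c]
        if len(pts) > 1:
            max_diam = max(max_diam, float(pdist(pts).max()))
    min_sep = np.inf
    for i, a in enumerate(uniq):
        for b in uniq[i + 1 :]:
            min_sep = min(min_sep, float(cdist(X[labels == a], X[labels == b]).min()))
    if max_diam == 0.0:
        return _DUNN_CAP if min_sep > 0 else 0.0
    return min(float(min_sep / max_diam), _DUNN_CAP)


def validity_indices(
    X: np.ndarray, labels: np.ndarray, names: tuple[str, ...] | None = None
) -> dict[str, float]:
    """Evaluate the partition indices for one labeling.

    Indices undefined for the labeling (single cluster, or a non-finite
    score) come back as NaN and are excluded from any vote. The gap
    statistic is not computed here (it needs the whole k range and reference
    draws); see :func:`gap_statistic`.
    """
    names = names or tuple(n for n in DEFAULT_INDICES if n != "gap")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    k = len(np.unique(labels))
    out: dict[str, float] = {}
    for name in names:
        if name == "gap":
            continue
        if k < 2:
            out[name] = np.nan
            continue
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                if name == "silhouette":
                    val = silhouette(X, labels)
                elif name == "calinski_harabasz":
                    val = float(calinski_harabasz_score(X, labels))
                    if not np.isfinite(val) and val > 0:
                        pass  # +inf = perfectly tight clusters, keep
                elif name == "davies_bouldin":
                    val = float(davies_bouldin_score(X, labels))
                elif name == "dunn":
                    val = dunn_index(X, labels)
                else:
                    raise ValueError(f"unknown validity index {name!r}")
        except ValueError as exc:
            if "unknown validity index" in str(exc):
                raise
            val = np.nan
        if name == "davies_bouldin" and np.isnan(val):
            val = np.inf  # worst for a lower-is-better index
        out[name] = val
    return out


@dataclass(frozen=True)
class GapResult:
    ks: np.ndarray
    gap: np.ndarray
    s: np.ndarray
    k_star: int


def _within_ss(X: np.ndarray, k: int, n_starts: int, seed: int | None) -> float:
    if k == 1:
        return float(((X - X.mean(axis=0)) ** 2).sum())
    return kmeans(X, k, n_starts=n_starts, seed=seed).sse


def gap_statistic(
    X: np.ndarray,
    ks: np.ndarray | list[int],
    null_reps: int = 50,
    seed: int | None = None,
    n_starts: int = 25,
    ref_starts: int | None = None,
    data_ss: dict[int, float] | None = None,
) -> GapResult:
    """Gap statistic with uniform reference nulls over the bounding box.

    gap(k) = mean_b log W*_kb - log W_k; the standard one-standard-error
    rule picks the smallest k with gap(k) >= gap(k+1) - s(k+1) (falling back
    to argmax). Reference fits use fewer restarts than data fits: the nulls
    only need the typical, not the optimal, within-dispersion.
    """
    X = np.asarray(X, dtype=float)
    ks = np.asarray(sorted(ks), dtype=int)
    rng = np.random.default_rng(seed)
    ref_starts = ref_starts or max(1, n_starts // 5)
    tiny = 1e-12  # floor before log: coincident clusters give W = 0

    logW = np.array(
        [
            np.log(max((data_ss or {}).get(int(k), _within_ss(X, int(k), n_starts, seed)), tiny))
            for k in ks
        ]
    )
    lo, hi = X.min(axis=0), X.max(axis=0)
    logWref = np.empty((null_reps, len(ks)))
    for b in range(null_reps):
        ref = rng.uniform(lo, hi, size=X.shape)
        ref_seed = int(rng.integers(2**31))
        for j, k in enumerate(ks):
            logWref[b, j] = np.log(max(_within_ss(ref, int(k), ref_starts, ref_seed), tiny))
    gap = logWref.mean(axis=0) - logW
    s = logWref.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / null_reps)

    k_star = int(ks[int(np.argmax(gap))])
    for j in range(len(ks) - 1):
        if gap[j] >= gap[j + 1] - s[j + 1]:
            k_star = int(ks[j])
            break
    return GapResult(ks, gap, s, k_star)


def _plurality(votes: dict[str, int]) -> int:
    """Plurality winner over index votes; ties resolve to the smallest k."""
    if not votes:
        raise ValueError("no index produced a vote")
    tally: dict[int, int] = {}
    for k in votes.values():
        tally[k] = tally.get(k, 0) + 1
    best = max(tally.values())
    return min(k for k, c in tally.items() if c == best)


@dataclass
class SelectKResult:
    k: int
    votes: dict[str, int]
    table: pd.DataFrame = field(default=None, repr=False)  # type: ignore[assignment]
    gap: GapResult | None = field(default=None, repr=False)


def select_k(
    X: np.ndarray,
    k_min: int,
    k_max: int,
    indices: tuple[str, ...] | None = None,
    n_starts: int = 25,
    null_reps: int = 50,
    seed: int | None = None,
) -> SelectKResult:
    """Choose the number of clusters by a validity-index plurality vote.

    Candidate k runs from ``k_min`` to ``k_max`` (truncated with a warning
    if it exceeds the number of observations). With ``k_min == 1`` the gap
    statistic first decides whether any partition beats a single cluster;
    only if it elects k >= 2 do the partition indices vote.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    indices = tuple(indices) if indices else DEFAULT_INDICES
    if k_min < 1 or k_max < k_min:
        raise ValueError("need 1 <= k_min <= k_max")
    if k_max > n:
        warnings.warn(f"k_max {k_max} exceeds n={n}; truncating", stacklevel=2)
        k_max = n
        k_min = min(k_min, k_max)
    if k_max == 1 or n < 2:
        return SelectKResult(1, {"trivial": 1})

    part_ks = list(range(max(2, k_min), k_max + 1))
    fits = {k: kmeans(X, k, n_starts=n_starts, seed=seed) for k in part_ks}

    gap_res: GapResult | None = None
    if "gap" in indices or k_min == 1:
        gap_ks = list(range(k_min, k_max + 1))
        gap_res = gap_statistic(
            X,
            gap_ks,
            null_reps=null_reps,
            seed=seed,
            n_starts=n_starts,
            data_ss={k: f.sse for k, f in fits.items()},
        )
        if k_min == 1 and gap_res.k_star == 1:
            return SelectKResult(1, {"gap": 1}, gap=gap_res)

    rows = {k: validity_indices(X, fits[k].labels, indices) for k in part_ks}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()

    votes: dict[str, int] = {}
    for name in indices:
        if name == "gap":
            if gap_res is not None:
                votes["gap"] = max(gap_res.k_star, min(part_ks))
            continue
        col = table[name].to_numpy()
        finite = np.isfinite(col) | ((name == "calinski_harabasz") & np.isposinf(col))
        if not finite.any():
            logger.info("index %s undefined over the whole range; excluded", name)
            continue
        work = col.copy()
        if name == "davies_bouldin":
            work[~np.isfinite(work)] = np.inf
            votes[name] = int(table.index[int(np.argmin(work))])
        else:
            work[np.isnan(work)] = -np.inf
            votes[name] = int(table.index[int(np.argmax(work))])
    return SelectKResult(_plurality(votes), votes, table, gap_res)
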