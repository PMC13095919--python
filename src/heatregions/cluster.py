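"""Two-stage clustering of per-cell apparent-temperature series.

Stage 1: columns (days) are standardized, a PCA of the correlation matrix
retains components with eigenvalue above the Kaiser threshold (> 1.0), and
k-means with randomized restarts groups the cells; the number of clusters is
voted by an ensemble of validity indices over a configured range. Stage 2
repeats the whole procedure independently inside each stage-1 cluster (with
the subcluster range allowing 1, i.e. "no substructure", decided by the gap
statistic), producing composite leaf labels "s1.s2".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "PCAResult",
    "KMeansFit",
    "ClusterLabeling",
    "standardize",
    "pca",
    "kmeans",
    "two_stage_cluster",
]

# fixed offsets fanning a master seed out to sub-stages (kept below 2**31)
_SEED_MOD = 2**31
_STAGE2_SEED_OFFSET = 104729


def standardize(X: np.ndarray, return_mask: bool = False):
    """Column-standardize to mean 0 and unit sample variance (ddof=1).

    Zero-variance columns carry no contrast and are dropped with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least two rows")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} zero-variance column(s)", stacklevel=2
        )
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    return (Xs, keep) if return_mask else Xs


@dataclass(frozen=True)
class PCAResult:
    """Eigenstructure of the correlation matrix of the standardized input."""

    eigenvalues: np.ndarray  # descending
    loadings: np.ndarray  # variables x components
    scores: np.ndarray  # observations x components
    n_retained: int
    retention_threshold: float

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.n_retained]

    def cumulative_variance(self) -> np.ndarray:
        return np.cumsum(self.eigenvalues) / self.eigenvalues.sum()

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "component": np.arange(1, len(self.eigenvalues) + 1),
                "eigenvalue": self.eigenvalues,
                "cumulative_variance": self.cumulative_variance(),
                "retained": np.arange(len(self.eigenvalues)) < self.n_retained,
            }
        )


def pca(Xs: np.ndarray, retention_threshold: float = 1.0) -> PCAResult:
    """PCA of a column-standardized matrix via SVD.

    Because columns are standardized with ddof=1, ``Xs.T @ Xs / (n-1)`` is
    the correlation matrix, so the squared singular values over ``n-1`` are
    its eigenvalues and the trace identity sum(eig) = n_columns holds.
    Components whose eigenvalue exceeds ``retention_threshold`` (Kaiser rule
    at the default 1.0) are marked retained. Loading signs are fixed so each
    component's largest-magnitude loading is positive.
    """
    Xs = np.asarray(Xs, dtype=float)
    if Xs.ndim != 2 or Xs.shape[0] < 2:
        raise ValueError("need at least two observations")
    n = Xs.shape[0]
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    eig = S**2 / (n - 1)
    loadings = Vt.T
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip
    scores = Xs @ loadings
    n_retained = int((eig > retention_threshold).sum())
    if n_retained == 0:
        # degenerate (all eigenvalues at/below threshold): keep the leading one
        n_retained = 1
    return PCAResult(eig, loadings, scores, n_retained, retention_threshold)


@dataclass(frozen=True)
class KMeansFit:
    k: int
    centroids: np.ndarray
    labels: np.ndarray  # 0-based cluster index per observation
    sse: float
    n_starts: int
    seed: int | None


def _lloyd(X: np.ndarray, centroids: np.ndarray, max_iter: int) -> tuple[np.ndarray, np.ndarray, float]:
    k = len(centroids)
    labels = np.full(len(X), -1)
    for _ in range(max_iter):
        d2 = cdist(X, centroids, "sqeuclidean")
        new_labels = d2.argmin(axis=1)  # argmin ties -> lowest cluster index
        # empty-cluster repair: reseed at the point farthest from its centroid
        for c in range(k):
            if not np.any(new_labels == c):
                far = d2[np.arange(len(X)), new_labels].argmax()
                centroids[c] = X[far]
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            members = labels == c
            if members.any():  # repair may have emptied a singleton donor
                centroids[c] = X[members].mean(axis=0)
    d2 = cdist(X, centroids, "sqeuclidean")
    sse = float(d2[np.arange(len(X)), labels].sum())
    return centroids, labels, sse


def kmeans(
    X: np.ndarray,
    k: int,
    n_starts: int = 25,
    max_iter: int = 300,
    seed: int | None = None,
) -> KMeansFit:
    """Best-of-``n_starts`` Lloyd k-means with randomized starting points.

    Starts draw k distinct observations as initial centroids; the restart
    with the lowest within-cluster sum of squares wins (first such restart
    on ties). Deterministic given ``seed``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(X)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for _ in range(n_starts):
        init = X[rng.choice(n, size=k, replace=False)].copy()
        centroids, labels, sse = _lloyd(X, init, max_iter)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, centroids.copy(), labels.copy())
    assert best is not None
    sse, centroids, labels = best
    return KMeansFit(k, centroids, labels, sse, n_starts, seed)


@dataclass
class ClusterLabeling:
    """Composite two-stage labels per cell."""

    frame: pd.DataFrame  # columns: cell_id, stage1, stage2, composite
    stage1_k: int = 0
    stage2_k: dict[int, int] = field(default_factory=dict)
    stage1_votes: dict[str, int] = field(default_factory=dict)
    stage2_votes: dict[int, dict[str, int]] = field(default_factory=dict)
    pca_summary: pd.DataFrame | None = None

    @property
    def composite(self) -> np.ndarray:
        return self.frame["composite"].to_numpy()

    @property
    def n_leaves(self) -> int:
        return self.frame["composite"].nunique()


def two_stage_cluster(
    X: np.ndarray,
    cell_ids: np.ndarray | None = None,
    stage1_range: tuple[int, int] = (10, 20),
    stage2_range: tuple[int, int] = (1, 10),
    retention_threshold: float = 1.0,
    n_starts: int = 25,
    null_reps: int = 50,
    seed: int | None = None,
    indices: tuple[str, ...] | None = None,
) -> ClusterLabeling:
    """Cluster series in two independent stages with validity-voted k.

    ``X`` is the raw cells x days matrix. Stage 2 re-derives standardization
    and PCA from the member cells of each stage-1 cluster rather than slicing
    stage-1 scores, and its k range may include 1 (decided by the gap
    statistic). Stage-1 clusters with fewer than 2 cells are forced to a
    single leaf and logged. Labels in the output are 1-based, composites are
    "s1.s2" strings.
    """
    from .validity import select_k

    X = np.asarray(X, dtype=float)
    n = len(X)
    if cell_ids is None:
        cell_ids = np.arange(n)
    base_seed = 0 if seed is None else int(seed) % _SEED_MOD

    Xs = standardize(X)
    p1 = pca(Xs, retention_threshold)
    S1 = p1.retained_scores
    sel1 = select_k(
        S1, *stage1_range, n_starts=n_starts, null_reps=null_reps, seed=base_seed, indices=indices
    )
    fit1 = kmeans(S1, sel1.k, n_starts=n_starts, seed=base_seed)

    stage1 = fit1.labels + 1
    stage2 = np.zeros(n, dtype=int)
    stage2_k: dict[int, int] = {}
    stage2_votes: dict[int, dict[str, int]] = {}
    for c in range(1, sel1.k + 1):
        members = np.flatnonzero(stage1 == c)
        sub_seed = (base_seed + _STAGE2_SEED_OFFSET * c) % _SEED_MOD
        if len(members) < 2:
            logger.info("stage-1 cluster %d has <2 cells; forcing a single leaf", c)
            stage2[members] = 1
            stage2_k[c] = 1
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # within-cluster constant days are routine
            Xc = standardize(X[members])
        if Xc.shape[1] == 0:
            # all member series identical: no contrast, hence no substructure
            stage2[members] = 1
            stage2_k[c] = 1
            continue
        pc = pca(Xc, retention_threshold)
        Sc = pc.retained_scores
        k2_max = min(stage2_range[1], len(members))
        sel2 = select_k(
            Sc,
            stage2_range[0],
            k2_max,
            n_starts=n_starts,
            null_reps=null_reps,
            seed=sub_seed,
            indices=indices,
        )
        stage2_k[c] = sel2.k
        stage2_votes[c] = sel2.votes
        if sel2.k == 1:
            stage2[members] = 1
        else:
            fit2 = kmeans(Sc, sel2.k, n_starts=n_starts, seed=sub_seed)
            stage2[members] = fit2.labels + 1

    frame = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "stage1": stage1,
            "stage2": stage2,
            "composite": [f"{a}.{b}" for a, b in zip(stage1, stage2)],
        }
    )
    return ClusterLabeling(frame, sel1.k, stage2_k, sel1.votes, stage2_votes, p1.summary())
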