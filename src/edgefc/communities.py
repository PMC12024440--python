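"""k-means edge communities from eFC rows.

Each of the M rows of the eFC matrix is one observation; features (columns)
are standardized to unit variance before ordinary Euclidean k-means, which
is the conventional realization of "standardized Euclidean distance"
clustering (a weighted-distance k-means has no standard centroid update).
The sweep runs k over an inclusive range with repeated random restarts per
k; the restart with minimum inertia wins.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from sklearn.cluster import KMeans

from .edges import EdgeIndex, EFCMatrix

__all__ = ["EdgePartition", "KSweepResult", "cluster_edges", "sweep_k"]

_EMPTY_CLUSTER_RETRIES = 10


@dataclasses.dataclass
class EdgePartition:
    """Hard assignment of each edge to one of k communities (labels 1..k)."""

    labels: np.ndarray  # int array, length M, values in 1..k
    k: int
    inertia: float
    restart_seed: int
    edge_index: EdgeIndex

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != (self.edge_index.n_edges,):
            raise ValueError("label vector length does not match edge index")
        if self.labels.min() < 1 or self.labels.max() > self.k:
            raise ValueError("labels must lie in 1..k")

    @property
    def n_edges(self) -> int:
        return self.labels.size


@dataclasses.dataclass
class KSweepResult:
    """Best partition and per-restart inertias for each k in a sweep."""

    partitions: dict[int, EdgePartition]
    restart_inertias: dict[int, list[float]]
    k_range: tuple[int, int]
    n_restarts: int

    def suggest_k(self) -> int:
        """k with the largest relative drop of the best-inertia curve."""
        ks = sorted(self.partitions)
        if len(ks) < 2:
            return ks[0]
        best = np.array([self.partitions[k].inertia for k in ks])
        prev = best[:-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            drop = np.where(prev > 0, (prev - best[1:]) / prev, 0.0)
        return ks[1 + int(np.argmax(drop))]


def _standardize_features(values: np.ndarray) -> np.ndarray:
    """Scale each eFC column to unit variance (population convention).

    Centering is irrelevant for k-means (translation invariance) but is
    applied for numerical hygiene.  Constant columns are left unscaled.
    """
    x = np.asarray(values, dtype=np.float64)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (x - mu) / sd


def cluster_edges(
    efc: EFCMatrix,
    k: int,
    n_restarts: int = 250,
    seed: int = 0,
) -> EdgePartition:
    """Cluster eFC rows into k communities; return the min-inertia restart.

    Deterministic given (efc, k, n_restarts, seed).  A restart that comes
    back with an empty community (possible in principle, though Lloyd's
    update relocates empty centroids) is re-initialized from a fresh derived
    seed, up to a bounded number of retries.
    """
    part, _ = _cluster_with_inertias(efc, k, n_restarts, seed)
    return part


def _cluster_with_inertias(
    efc: EFCMatrix, k: int, n_restarts: int, seed: int
) -> tuple[EdgePartition, list[float]]:
    m = efc.edge_index.n_edges
    if not (2 <= k <= m):
        raise ValueError(f"k must be in [2, M={m}], got {k}")
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    x = _standardize_features(efc.values)
    ss = np.random.SeedSequence([seed, k])
    restart_seeds = ss.generate_state(n_restarts * (_EMPTY_CLUSTER_RETRIES + 1))
    best: tuple[float, np.ndarray, int] | None = None
    inertias: list[float] = []
    pos = 0
    for _ in range(n_restarts):
        labels = None
        inertia = np.inf
        used = -1
        for _retry in range(_EMPTY_CLUSTER_RETRIES + 1):
            rs = int(restart_seeds[pos]) % (2**32)
            pos += 1
            km = KMeans(
                n_clusters=k,
                n_init=1,
                init="k-means++",
                algorithm="lloyd",
                random_state=rs,
            ).fit(x)
            if np.unique(km.labels_).size == k:
                labels, inertia, used = km.labels_, float(km.inertia_), rs
                break
        if labels is None:
            raise RuntimeError(
                f"k-means produced an empty community in "
                f"{_EMPTY_CLUSTER_RETRIES + 1} consecutive initializations (k={k})"
            )
        inertias.append(inertia)
        if best is None or inertia < best[0]:
            best = (inertia, labels, used)
    assert best is not None
    inertia, labels, used_seed = best
    part = EdgePartition(
        labels=labels + 1,
        k=k,
        inertia=inertia,
        restart_seed=used_seed,
        edge_index=efc.edge_index,
    )
    return part, inertias


def sweep_k(
    efc: EFCMatrix,
    k_range: tuple[int, int] = (2, 10),
    n_restarts: int = 250,
    seed: int = 0,
) -> KSweepResult:
    """Run cluster_edges for every k in the inclusive range.

    The restart budget applies per k.  Each k derives its restart seeds from
    (seed, k), so per-k results are independent of the range requested.
    """
    lo, hi = k_range
    if lo < 2 or hi < lo:
        raise ValueError(f"invalid k range {k_range}")
    partitions: dict[int, EdgePartition] = {}
    inertias: dict[int, list[float]] = {}
    for k in range(lo, hi + 1):
        part, restarts = _cluster_with_inertias(efc, k, n_restarts, seed)
        partitions[k] = part
        inertias[k] = restarts
    return KSweepResult(
        partitions=partitions,
        restart_inertias=inertias,
        k_range=(lo, hi),
        n_restarts=n_restarts,
    )
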