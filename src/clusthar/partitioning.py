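"""Unsupervised partitioning of training samples.

The confusion analysis upstream of the hierarchical recognizer needs a
k-group partition of the training set; k defaults to the number of
predefined activities. Three algorithms are supported: k-means (Lloyd,
seeded restarts), k-medoids (seeded Voronoi iteration over a precomputed
distance matrix) and agglomerative clustering with Ward linkage.

Cosine and correlation geometries are supported for the centroid-based
algorithms: k-means uses the standard spherical-k-means equivalence
(row-normalise, or row-centre-then-normalise, then run Euclidean k-means);
k-medoids applies the similarity directly as the medoid distance. Ward
linkage is defined only for Euclidean geometry, so requesting it with
another metric is a configuration error rather than a silent substitution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import AgglomerativeClustering, KMeans

from .errors import DataError, InvalidSpecError

_ALGORITHMS = ("kmeans", "kmedoids", "agglomerative")
_METRICS = ("euclidean", "cosine", "correlation")


@dataclass(frozen=True)
class PartitionSpec:
    """Configuration of the partitioning step.

    ``cluster_count_offset`` is relative to the number of activities:
    0 means k equals the activity count, -1 one fewer, +1 one more.
    ``n_restarts`` seeds the centroid-based algorithms; agglomerative
    clustering is deterministic and ignores both seed and restarts.
    ``scale`` optionally z-scores columns first (off by default: the
    benchmark feature tables arrive pre-normalised).
    """

    algorithm: str = "kmeans"
    metric: str = "euclidean"
    cluster_count_offset: int = 0
    seed: int = 0
    max_iterations: int = 300
    n_restarts: int = 10
    scale: bool = False

    def __post_init__(self) -> None:
        if self.algorithm not in _ALGORITHMS:
            raise InvalidSpecError(f"unknown algorithm {self.algorithm!r}")
        if self.metric not in _METRICS:
            raise InvalidSpecError(f"unknown metric {self.metric!r}")
        if self.algorithm == "agglomerative" and self.metric != "euclidean":
            raise InvalidSpecError(
                "Ward-linkage agglomerative clustering is defined only for the "
                f"euclidean metric, not {self.metric!r}"
            )
        if self.max_iterations < 1:
            raise InvalidSpecError("max_iterations must be positive")
        if self.n_restarts < 1:
            raise InvalidSpecError("n_restarts must be positive")

    def resolve_k(self, n_activities: int, n_samples: int) -> int:
        k = n_activities + self.cluster_count_offset
        if k < 1:
            raise InvalidSpecError(f"k = {n_activities} + {self.cluster_count_offset} < 1")
        if k > n_samples:
            raise InvalidSpecError(f"k = {k} exceeds the {n_samples} samples")
        return k


@dataclass(frozen=True)
class ClusterPartition:
    """Per-sample cluster identifiers in ``0..k-1``.

    ``objective`` is the algorithm's internal criterion at convergence
    (within-cluster sum of squares for k-means, total point-to-medoid
    distance for k-medoids, absent for agglomerative). ``events`` records
    empty-cluster repairs.
    """

    assignment: np.ndarray
    k: int
    objective: float | None = None
    events: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        if a.ndim != 1:
            raise InvalidSpecError("assignment must be one id per sample")
        if a.size and (a.min() < 0 or a.max() >= self.k):
            raise InvalidSpecError("cluster ids must lie in 0..k-1")
        object.__setattr__(self, "assignment", a)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == cluster_id)

    def write_tsv(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_index\tcluster_id\n")
            for i, c in enumerate(self.assignment):
                fh.write(f"{i}\t{c}\n")


def _validate_features(x: np.ndarray, metric: str) -> None:
    if not np.isfinite(x).all():
        bad = int(np.flatnonzero(~np.isfinite(x).all(axis=1))[0])
        raise DataError(f"non-finite feature value in row {bad}")
    if metric in ("cosine", "correlation"):
        centered = x - x.mean(axis=1, keepdims=True) if metric == "correlation" else x
        norms = np.linalg.norm(centered, axis=1)
        if (norms == 0).any():
            bad = int(np.flatnonzero(norms == 0)[0])
            what = "constant-valued" if metric == "correlation" else "all-zero"
            raise DataError(f"{metric} metric undefined for {what} row {bad}")


def _transform(x: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return x
    y = x - x.mean(axis=1, keepdims=True) if metric == "correlation" else x
    return y / np.linalg.norm(y, axis=1, keepdims=True)


def _kmedoids(dist: np.ndarray, k: int, seed: int, n_restarts: int, max_iter: int):
    """Voronoi-iteration k-medoids on a dense distance matrix.

    Assignment ties and medoid-update ties break toward the lowest index,
    which keeps duplicated rows in the same cluster and makes runs with a
    fixed seed byte-identical.
    """
    n = dist.shape[0]
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, list[str]] | None = None
    for _ in range(n_restarts):
        medoids = np.sort(rng.choice(n, size=k, replace=False))
        events: list[str] = []
        for _ in range(max_iter):
            assign = np.argmin(dist[:, medoids], axis=1)
            for c in range(k):
                if not (assign == c).any():
                    # revive the empty cluster with the sample farthest
                    # from its current medoid
                    far = int(np.argmax(dist[np.arange(n), medoids[assign]]))
                    assign[far] = c
                    events.append(f"empty cluster {c} repaired with sample {far}")
            new_medoids = medoids.copy()
            for c in range(k):
                idx = np.flatnonzero(assign == c)
                within = dist[np.ix_(idx, idx)].sum(axis=1)
                new_medoids[c] = idx[int(np.argmin(within))]
            if np.array_equal(new_medoids, medoids):
                break
            medoids = new_medoids
        assign = np.argmin(dist[:, medoids], axis=1)
        obj = float(dist[np.arange(n), medoids[assign]].sum())
        if best is None or obj < best[0]:
            best = (obj, assign, events)
    assert best is not None
    return best[1], best[0], tuple(best[2])


def partition(features: np.ndarray, spec: PartitionSpec, n_activities: int) -> ClusterPartition:
    """Partition samples into ``k = n_activities + offset`` clusters.

    Deterministic for a fixed seed. Raises :class:`InvalidSpecError` when
    k is out of range and :class:`DataError` on non-finite input or rows
    for which the requested similarity is undefined.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2:
        raise DataError("features must be a 2-D matrix")
    k = spec.resolve_k(n_activities, x.shape[0])
    _validate_features(x, spec.metric)
    if spec.scale:
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd

    if x.shape[0] == k:  # one sample per cluster: assignment is forced
        return ClusterPartition(np.arange(k), k)

    if spec.algorithm == "kmeans":
        xt = _transform(x, spec.metric)
        km = KMeans(
            n_clusters=k,
            n_init=spec.n_restarts,
            max_iter=spec.max_iterations,
            random_state=spec.seed,
        ).fit(xt)
        labels, obj, events = km.labels_, float(km.inertia_), ()
    elif spec.algorithm == "kmedoids":
        dist = squareform(pdist(x, metric=spec.metric))
        labels, obj, events = _kmedoids(
            dist, k, spec.seed, spec.n_restarts, spec.max_iterations
        )
    else:
        agg = AgglomerativeClustering(n_clusters=k, linkage="ward").fit(x)
        labels, obj, events = agg.labels_, None, ()

    # contiguity repair: relabel so ids are 0..k'-1, then top up to k
    uniq = np.unique(labels)
    remap = {c: i for i, c in enumerate(uniq)}
    labels = np.array([remap[c] for c in labels])
    events = tuple(events)
    while len(np.unique(labels)) < k:  # defensive; sklearn never returns empties
        cid = len(np.unique(labels))
        far = int(np.argmax(np.bincount(labels)))
        idx = np.flatnonzero(labels == far)
        labels[idx[-1]] = cid
        events = events + (f"empty cluster {cid} repaired with sample {idx[-1]}",)
    return ClusterPartition(labels, k, objective=obj, events=events)


def with_offset(spec: PartitionSpec, offset: int) -> PartitionSpec:
    return replace(spec, cluster_count_offset=offset)
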