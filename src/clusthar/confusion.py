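"""Cluster-purity confusion analysis.

The central quantity is the *activity confusion index*: partition the
labeled training set into k clusters, name each cluster after its majority
activity, and count, for every ordered activity pair (j, i), the samples
truly labeled j that sit in clusters named i. Arranged as a |L|×|L| matrix
CM (rows = true activity, columns = cluster-majority activity) this gives a
data-driven, annotation-free picture of which activities the sensor
features cannot tell apart.

Column-normalising CM yields the confusion ratio
``eta(j, i) = CM[j, i] / sum_j CM[j, i]``; thresholding the ratios at a
confusion threshold theta produces, for each activity A, the *confusing
set* ``S(A) = { B != A : eta(B, A) >= theta }`` — the activities a
recognizer that just predicted A plausibly mistook it for. Non-empty
confusing sets are what trigger second-level classifiers in the
hierarchical recognizer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .errors import (
    ConsistencyError,
    EmptyClusterError,
    InvalidThresholdError,
)
from .partitioning import ClusterPartition


@dataclass(frozen=True)
class ActivityConfusionMatrix:
    """|L|×|L| integer matrix of activity confusion indices.

    ``counts[j, i]`` is the number of samples with true activity
    ``label_order[j]`` lying in clusters whose majority activity is
    ``label_order[i]``. Diagonal entries are stored (a cluster's majority
    class contributes to its own column) but never enter confusing sets.
    """

    counts: np.ndarray
    label_order: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        n = len(self.label_order)
        if c.shape != (n, n):
            raise ConsistencyError(f"counts shape {c.shape} != ({n}, {n})")
        if (c < 0).any() or not np.issubdtype(c.dtype, np.integer):
            c = c.astype(float)
            if (c < 0).any() or (c != np.round(c)).any():
                raise ConsistencyError("counts must be nonnegative integers")
            c = c.astype(int)
        object.__setattr__(self, "counts", c.astype(int))
        object.__setattr__(self, "label_order", tuple(self.label_order))

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ActivityConfusionMatrix)
            and self.label_order == other.label_order
            and np.array_equal(self.counts, other.counts)
        )

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.label_order, columns=self.label_order)

    def write_tsv(self, path: Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: Path) -> "ActivityConfusionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if list(df.index) != list(df.columns):
            raise ConsistencyError("row and column activity names differ")
        return cls(df.to_numpy(), tuple(df.columns))


@dataclass(frozen=True)
class ConfusionRatioMatrix:
    """Column-normalised confusion matrix; all-zero columns stay zero."""

    ratios: np.ndarray
    label_order: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ratios, index=self.label_order, columns=self.label_order)

    def write_tsv(self, path: Path) -> None:
        self.to_frame().to_csv(path, sep="\t")


@dataclass(frozen=True)
class ConfusingSetMap:
    """Per-activity confusing sets at a fixed threshold theta.

    ``sets[A]`` is a tuple (ordered by the label order, for reproducible
    output) of the activities B != A whose confusion ratio toward A meets
    theta. Activities with empty sets need no second-level classifier.
    """

    sets: Mapping[str, tuple[str, ...]]
    threshold: float
    label_order: tuple[str, ...]

    def __post_init__(self) -> None:
        for a, s in self.sets.items():
            if a in s:
                raise ConsistencyError(f"{a} cannot be its own confuser")
            unknown = set(s) - set(self.label_order)
            if unknown:
                raise ConsistencyError(f"unknown activities in S({a}): {sorted(unknown)}")

    def __getitem__(self, activity: str) -> tuple[str, ...]:
        return self.sets[activity]

    def nonempty(self) -> tuple[str, ...]:
        return tuple(a for a in self.label_order if self.sets.get(a))

    def as_sets(self) -> dict[str, frozenset]:
        return {a: frozenset(s) for a, s in self.sets.items()}

    def write_tsv(self, path: Path) -> None:
        with open(path, "w") as fh:
            fh.write("activity\tconfusing_activities\n")
            for a in self.label_order:
                fh.write(f"{a}\t{','.join(self.sets.get(a, ()))}\n")

    @classmethod
    def read_tsv(cls, path: Path, threshold: float = float("nan")) -> "ConfusingSetMap":
        order: list[str] = []
        sets: dict[str, tuple[str, ...]] = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                a, _, rest = line.rstrip("\n").partition("\t")
                order.append(a)
                sets[a] = tuple(x for x in rest.split(",") if x)
        return cls(sets, threshold, tuple(order))


def discovered_groups(sets: ConfusingSetMap) -> frozenset:
    """Activity grouping implied by the confusing sets.

    Two activities belong to the same group when either's confusing set
    names the other, directly or transitively (connected components of the
    undirected confusion graph). An activity's own column can be all-zero
    — it was never any cluster's majority — yet its groupmates' sets still
    link it, so the component view recovers groupings that per-activity
    sets alone understate.
    """
    parent = {a: a for a in sets.label_order}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, members in sets.sets.items():
        for b in members:
            parent[find(a)] = find(b)
    groups: dict[str, set] = {}
    for a in sets.label_order:
        groups.setdefault(find(a), set()).add(a)
    return frozenset(frozenset(g) for g in groups.values())


def majority_label(member_labels: Iterable[str], label_order: Sequence[str]) -> str:
    """Majority activity of a cluster; ties break toward the earliest
    activity in ``label_order``."""
    members = list(member_labels)
    if not members:
        raise EmptyClusterError("cannot take the majority label of an empty cluster")
    rank = {a: r for r, a in enumerate(label_order)}
    unknown = set(members) - set(rank)
    if unknown:
        raise ConsistencyError(f"labels outside the label set: {sorted(unknown)}")
    counts: dict[str, int] = {}
    for m in members:
        counts[m] = counts.get(m, 0) + 1
    return max(counts, key=lambda a: (counts[a], -rank[a]))


def activity_confusion_matrix(
    dataset: LabeledDataset, part: ClusterPartition
) -> ActivityConfusionMatrix:
    """Tally the activity confusion index over all clusters.

    Every sample contributes exactly one count: to the row of its true
    activity and the column of its cluster's majority activity. The entry
    total therefore equals the number of clustered samples, and row j sums
    to the number of training samples labeled j.
    """
    if part.assignment.shape[0] != dataset.n_samples:
        raise ConsistencyError(
            f"partition covers {part.assignment.shape[0]} samples, "
            f"dataset has {dataset.n_samples}"
        )
    order = dataset.label_set
    idx = {a: i for i, a in enumerate(order)}
    counts = np.zeros((len(order), len(order)), dtype=int)
    labels = dataset.labels.astype(str)
    for c in range(part.k):
        members = part.members(c)
        if members.size == 0:
            continue
        maj = majority_label(labels[members], order)
        col = idx[maj]
        rows, tallies = np.unique(labels[members], return_counts=True)
        for a, t in zip(rows, tallies):
            counts[idx[a], col] += int(t)
    return ActivityConfusionMatrix(counts, tuple(order))


def confusion_ratios(cm: ActivityConfusionMatrix) -> ConfusionRatioMatrix:
    """Normalise each CM column to sum to one; all-zero columns map to
    all-zero ratio columns (the activity was never any cluster's majority,
    so it acquires no confusers)."""
    counts = cm.counts.astype(float)
    colsum = counts.sum(axis=0)
    ratios = np.divide(counts, colsum, out=np.zeros_like(counts), where=colsum > 0)
    return ConfusionRatioMatrix(ratios, cm.label_order)


def confusing_sets(cm: ActivityConfusionMatrix, theta: float) -> ConfusingSetMap:
    """Threshold the confusion ratios into per-activity confusing sets.

    Membership uses ``eta(B, A) >= theta`` (the comparison is inclusive),
    with theta restricted to (0, 1].
    """
    if not (0.0 < theta <= 1.0):
        raise InvalidThresholdError(f"theta must lie in (0, 1], got {theta}")
    eta = confusion_ratios(cm).ratios
    order = cm.label_order
    sets = {
        a: tuple(
            b for j, b in enumerate(order) if b != a and eta[j, i] >= theta
        )
        for i, a in enumerate(order)
    }
    return ConfusingSetMap(sets, theta, order)
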