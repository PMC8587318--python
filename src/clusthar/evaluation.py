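"""Recognition metrics and sensitivity sweeps.

Accuracy, macro-averaged precision and recall, and F1 computed as the
harmonic mean of macro precision and macro recall (note: this differs from
averaging per-class F1 scores). Averaging over classes is unweighted
(macro); classes absent from a test fold contribute zero with a warning.

``run_sweep`` re-runs the full training pipeline while varying one axis —
confusion threshold, cluster-count offset, distance metric, clustering
algorithm, or (top, second) classifier pairing — with every other setting
and every seed held fixed, and keeps the per-row confusion provenance so
threshold monotonicity and flat-equivalence can be checked mechanically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_score, recall_score

from .data import LabeledDataset
from .errors import DataError, InvalidSpecError
from .hierarchy import (
    FAMILY_ALIASES,
    ClassifierSpec,
    FlatModel,
    HierarchicalRecognizer,
    fit_pipeline,
)
from .partitioning import PartitionSpec

SWEEP_AXES = (
    "threshold",
    "cluster_count_offset",
    "distance_metric",
    "clustering_algorithm",
    "classifier_pair",
)


@dataclass(frozen=True)
class MetricsReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class_confusion: np.ndarray
    label_order: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": [self.accuracy, self.precision, self.recall, self.f1],
            },
            index=["accuracy", "precision", "recall", "f1"],
        )

    def write_tsv(self, path: Path) -> None:
        pct = (self.to_frame() * 100).round(2)
        pct.to_csv(path, sep="\t")

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.per_class_confusion, index=self.label_order, columns=self.label_order
        )


def evaluate(model: FlatModel | HierarchicalRecognizer, test: LabeledDataset) -> MetricsReport:
    """Score a fitted recognizer on a held-out labeled set."""
    if test.n_samples == 0:
        raise DataError("empty test set")
    order = model.label_set
    unknown = set(test.labels.astype(str)) - set(order)
    if unknown:
        raise DataError(f"test labels outside the training label set: {sorted(unknown)}")
    y_true = test.labels.astype(str)
    y_pred = model.predict(test.features).astype(str)
    cmat = _sk_confusion(y_true, y_pred, labels=list(order))
    missing = [a for a in order if (y_true == a).sum() == 0]
    if missing:
        warnings.warn(
            f"classes absent from the test fold contribute 0 to macro averages: {missing}",
            stacklevel=2,
        )
    acc = float(np.trace(cmat) / cmat.sum())
    prec = float(precision_score(y_true, y_pred, labels=list(order), average="macro", zero_division=0))
    rec = float(recall_score(y_true, y_pred, labels=list(order), average="macro", zero_division=0))
    f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    return MetricsReport(acc, prec, rec, f1, cmat, tuple(order))


@dataclass(frozen=True)
class SweepRow:
    value: object
    report: MetricsReport
    provenance: dict = field(compare=False, default_factory=dict)


@dataclass(frozen=True)
class SweepResult:
    axis: str
    rows: tuple[SweepRow, ...]

    def to_frame(self) -> pd.DataFrame:
        recs = [
            {
                "value": str(r.value),
                "accuracy": r.report.accuracy,
                "precision": r.report.precision,
                "recall": r.report.recall,
                "f1": r.report.f1,
            }
            for r in self.rows
        ]
        return pd.DataFrame(recs)

    def write_tsv(self, path: Path) -> None:
        df = self.to_frame()
        for c in ("accuracy", "precision", "recall", "f1"):
            df[c] = (df[c] * 100).round(2)
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything `fit_pipeline` needs, in one replaceable record."""

    partition_spec: PartitionSpec = PartitionSpec()
    theta: float = 0.01
    top_spec: ClassifierSpec = ClassifierSpec()
    second_spec: ClassifierSpec = ClassifierSpec()


def _validate_axis_values(axis: str, values: Sequence) -> None:
    if axis not in SWEEP_AXES:
        raise InvalidSpecError(f"unknown sweep axis {axis!r}")
    if not values:
        raise InvalidSpecError("sweep values must be non-empty")
    for v in values:
        if axis == "threshold" and not (0 < float(v) <= 1):
            raise InvalidSpecError(f"illegal threshold {v}")
        elif axis == "cluster_count_offset" and int(v) != v:
            raise InvalidSpecError(f"offset must be an integer, got {v}")
        elif axis == "distance_metric" and v not in ("euclidean", "cosine", "correlation"):
            raise InvalidSpecError(f"illegal metric {v!r}")
        elif axis == "clustering_algorithm" and v not in ("kmeans", "kmedoids", "agglomerative"):
            raise InvalidSpecError(f"illegal algorithm {v!r}")
        elif axis == "classifier_pair":
            try:
                p, q = v
            except (TypeError, ValueError):
                raise InvalidSpecError(f"classifier_pair values are (top, second) pairs, got {v!r}")
            for fam in (p, q):
                if FAMILY_ALIASES.get(fam, fam) not in ("naive_bayes", "knn", "svm_linear", "decision_tree"):
                    raise InvalidSpecError(f"unknown classifier family {fam!r}")


def _with_value(config: PipelineConfig, axis: str, value) -> PipelineConfig:
    if axis == "threshold":
        return replace(config, theta=float(value))
    if axis == "cluster_count_offset":
        return replace(config, partition_spec=replace(config.partition_spec, cluster_count_offset=int(value)))
    if axis == "distance_metric":
        return replace(config, partition_spec=replace(config.partition_spec, metric=value))
    if axis == "clustering_algorithm":
        return replace(config, partition_spec=replace(config.partition_spec, algorithm=value))
    p, q = value
    return replace(
        config,
        top_spec=replace(config.top_spec, family=FAMILY_ALIASES.get(p, p)),
        second_spec=replace(config.second_spec, family=FAMILY_ALIASES.get(q, q)),
    )


def run_sweep(
    train: LabeledDataset,
    test: LabeledDataset,
    base_config: PipelineConfig,
    axis: str,
    values: Sequence,
) -> SweepResult:
    """Vary one configuration axis, refitting and re-evaluating per value."""
    _validate_axis_values(axis, values)
    rows = []
    for v in values:
        cfg = _with_value(base_config, axis, v)
        rec = fit_pipeline(train, cfg.partition_spec, cfg.theta, cfg.top_spec, cfg.second_spec)
        rows.append(SweepRow(v, evaluate(rec, test), rec.provenance))
    return SweepResult(axis, tuple(rows))


def classifier_pair_grid() -> list[tuple[str, str]]:
    """The full 4×4 (top, second) family grid."""
    fams = ("naive_bayes", "knn", "svm_linear", "decision_tree")
    return [(p, q) for p in fams for q in fams]
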