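"""Two-level hierarchical recognizer with confusion-guided routing.

Training: a top-level classifier is fit on all activities (identical to
the conventional flat model); then, for every activity A whose confusing
set S(A) is non-empty, a second-level classifier is fit on exactly the
training samples whose true label lies in {A} ∪ S(A), using the full
feature vector. Prediction: the top-level label A is final when S(A) is
empty, otherwise the sample is routed to the second-level model for A,
whose output is final. The top and second levels may use different
classifier families (the heterogeneous "P-Q" pairing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import joblib
import numpy as np
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .confusion import (
    ConfusingSetMap,
    activity_confusion_matrix,
    confusing_sets,
    confusion_ratios,
)
from .data import LabeledDataset
from .errors import ConsistencyError, DataError, DegenerateDataError, InvalidSpecError
from .partitioning import PartitionSpec, partition

FAMILIES = ("naive_bayes", "knn", "svm_linear", "decision_tree")
#: short aliases used in "P-Q" pairing notation
FAMILY_ALIASES = {
    "nb": "naive_bayes",
    "knn": "knn",
    "svm": "svm_linear",
    "dt": "decision_tree",
}


@dataclass(frozen=True)
class ClassifierSpec:
    """One base-learner configuration.

    Defaults: 1-nearest-neighbour with Euclidean distance, linear-kernel
    SVM with C = 1, Gini decision tree with unlimited depth, Gaussian
    naive Bayes. The seed pins the tree's feature-tie behaviour.
    """

    family: str = "naive_bayes"
    n_neighbors: int = 1
    knn_metric: str = "euclidean"
    svm_c: float = 1.0
    tree_criterion: str = "gini"
    tree_max_depth: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        fam = FAMILY_ALIASES.get(self.family, self.family)
        if fam not in FAMILIES:
            raise InvalidSpecError(f"unknown classifier family {self.family!r}")
        object.__setattr__(self, "family", fam)

    def build(self):
        if self.family == "naive_bayes":
            return GaussianNB()
        if self.family == "knn":
            return KNeighborsClassifier(n_neighbors=self.n_neighbors, metric=self.knn_metric)
        if self.family == "svm_linear":
            return SVC(kernel="linear", C=self.svm_c, random_state=self.seed)
        return DecisionTreeClassifier(
            criterion=self.tree_criterion,
            max_depth=self.tree_max_depth,
            random_state=self.seed,
        )


@dataclass(frozen=True)
class FlatModel:
    """A fitted single-step recognizer over the full activity set."""

    estimator: object
    label_set: tuple[str, ...]
    spec: ClassifierSpec

    def predict(self, features: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(features, dtype=float))
        return self.estimator.predict(x).astype(object)


@dataclass(frozen=True)
class PredictionResult:
    final_label: str
    top_level_label: str
    routed: bool


@dataclass(frozen=True)
class HierarchicalRecognizer:
    top_model: FlatModel
    second_models: dict[str, FlatModel]
    confusing_sets: ConfusingSetMap
    label_set: tuple[str, ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def predict_detailed(self, features: np.ndarray) -> list[PredictionResult]:
        """Row-wise two-level routing; see the module docstring."""
        x = np.atleast_2d(np.asarray(features, dtype=float))
        if x.shape[1] != self.top_model.estimator.n_features_in_:
            raise DataError(
                f"feature width {x.shape[1]} != training width "
                f"{self.top_model.estimator.n_features_in_}"
            )
        top = self.top_model.predict(x)
        final = top.copy()
        routed = np.zeros(len(top), dtype=bool)
        for a, model in self.second_models.items():
            mask = top == a
            if mask.any():
                final[mask] = model.predict(x[mask])
                routed[mask] = True
        return [
            PredictionResult(str(f), str(t), bool(r))
            for f, t, r in zip(final, top, routed)
        ]

    def predict(self, features: np.ndarray) -> np.ndarray:
        return np.array([p.final_label for p in self.predict_detailed(features)], dtype=object)


def _check_trainable(dataset: LabeledDataset, spec: ClassifierSpec) -> None:
    present = [a for a, c in dataset.class_counts().items() if c > 0]
    if len(present) < 2:
        raise DegenerateDataError(
            f"training requires at least two classes, found {present}"
        )
    if spec.family == "knn" and dataset.n_samples < spec.n_neighbors:
        raise DegenerateDataError(
            f"knn needs at least {spec.n_neighbors} samples, got {dataset.n_samples}"
        )


def train_flat(dataset: LabeledDataset, spec: ClassifierSpec) -> FlatModel:
    """Fit a conventional one-step recognizer over all activities."""
    _check_trainable(dataset, spec)
    est = spec.build()
    est.fit(dataset.features, dataset.labels.astype(str))
    return FlatModel(est, dataset.label_set, spec)


def train_hierarchical(
    dataset: LabeledDataset,
    sets: ConfusingSetMap,
    top_spec: ClassifierSpec,
    second_spec: ClassifierSpec,
) -> HierarchicalRecognizer:
    """Fit the top-level model plus one second-level model per activity
    with a non-empty confusing set."""
    known = set(dataset.label_set)
    for a, s in sets.sets.items():
        missing = ({a} | set(s)) - known if s else set(s) - known
        if missing:
            raise ConsistencyError(f"confusing-set activities absent from dataset: {sorted(missing)}")
    counts = dataset.class_counts()
    top = train_flat(dataset, top_spec)
    second: dict[str, FlatModel] = {}
    for a in dataset.label_set:
        s = sets.sets.get(a, ())
        if not s:
            continue
        absent = [b for b in (a, *s) if counts.get(b, 0) == 0]
        if absent:
            raise ConsistencyError(f"no training samples for {absent} needed by S({a})")
        keep = np.isin(dataset.labels.astype(str), [a, *s])
        second[a] = train_flat(dataset.subset_rows(keep), second_spec)
    return HierarchicalRecognizer(top, second, sets, dataset.label_set)


def fit_pipeline(
    dataset: LabeledDataset,
    partition_spec: PartitionSpec,
    theta: float,
    top_spec: ClassifierSpec,
    second_spec: ClassifierSpec,
) -> HierarchicalRecognizer:
    """Full training pipeline: cluster, tally confusion, threshold,
    train the two-level recognizer. The confusion matrix, ratio matrix,
    confusing sets and partition are kept in ``provenance``."""
    part = partition(dataset.features, partition_spec, len(dataset.label_set))
    cm = activity_confusion_matrix(dataset, part)
    sets = confusing_sets(cm, theta)
    rec = train_hierarchical(dataset, sets, top_spec, second_spec)
    prov = {
        "partition": part,
        "cm": cm,
        "eta": confusion_ratios(cm),
        "sets": sets,
        "theta": theta,
        "partition_spec": partition_spec,
    }
    return replace(rec, provenance=prov)


# --- model bundle serialization -------------------------------------------

def save_bundle(rec: HierarchicalRecognizer, out_dir: Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "label_set": list(rec.label_set),
        "threshold": rec.confusing_sets.threshold,
        "top_spec": rec.top_model.spec.__dict__,
        "second_specs": {a: m.spec.__dict__ for a, m in rec.second_models.items()},
        "second_levels": list(rec.second_models),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    rec.confusing_sets.write_tsv(out / "confusing_sets.tsv")
    prov = rec.provenance
    if "cm" in prov:
        prov["cm"].write_tsv(out / "confusion_matrix.tsv")
        prov["eta"].write_tsv(out / "confusion_ratios.tsv")
    joblib.dump(rec.top_model, out / "top_model.joblib")
    for a, m in rec.second_models.items():
        joblib.dump(m, out / f"second_{a}.joblib")


def load_bundle(in_dir: Path) -> HierarchicalRecognizer:
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    sets = ConfusingSetMap.read_tsv(src / "confusing_sets.tsv", manifest["threshold"])
    top = joblib.load(src / "top_model.joblib")
    second = {
        a: joblib.load(src / f"second_{a}.joblib") for a in manifest["second_levels"]
    }
    return HierarchicalRecognizer(top, second, sets, tuple(manifest["label_set"]))
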