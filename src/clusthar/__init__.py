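"""Clustering-guided hierarchical activity recognition.

Quantifies pairwise confusion between activities from the purity of an
unsupervised partition of labeled wearable-sensor feature tables, derives
per-activity confusing sets at a ratio threshold, and trains a two-level
recognizer that routes predictions through specialized second-level
classifiers for confusable activities.
"""

from importlib import resources

from .confusion import (
    ActivityConfusionMatrix,
    ConfusingSetMap,
    ConfusionRatioMatrix,
    activity_confusion_matrix,
    confusing_sets,
    confusion_ratios,
    discovered_groups,
    majority_label,
)
from .data import (
    UCIHAR_ACTIVITY_KEY,
    DatasetLayout,
    LabeledDataset,
    load_dataset,
    write_dataset,
)
from .evaluation import (
    MetricsReport,
    PipelineConfig,
    SweepResult,
    evaluate,
    run_sweep,
)
from .hierarchy import (
    ClassifierSpec,
    FlatModel,
    HierarchicalRecognizer,
    PredictionResult,
    fit_pipeline,
    load_bundle,
    save_bundle,
    train_flat,
    train_hierarchical,
)
from .partitioning import ClusterPartition, PartitionSpec, partition
from .synthetic import SyntheticSpec, generate, planted_confusion_sets

__version__ = "0.1.0"


def benchmark_confusion_matrix() -> ActivityConfusionMatrix:
    """The packaged six-activity smartphone-benchmark activity confusion
    matrix (k-means partition of the 7352-sample training set)."""
    ref = resources.files("clusthar") / "fixtures" / "ucihar_activity_confusion.tsv"
    with resources.as_file(ref) as path:
        return ActivityConfusionMatrix.read_tsv(path)


__all__ = [
    "ActivityConfusionMatrix",
    "ClassifierSpec",
    "ClusterPartition",
    "ConfusingSetMap",
    "ConfusionRatioMatrix",
    "DatasetLayout",
    "FlatModel",
    "HierarchicalRecognizer",
    "LabeledDataset",
    "MetricsReport",
    "PartitionSpec",
    "PipelineConfig",
    "PredictionResult",
    "SweepResult",
    "SyntheticSpec",
    "UCIHAR_ACTIVITY_KEY",
    "activity_confusion_matrix",
    "benchmark_confusion_matrix",
    "confusing_sets",
    "confusion_ratios",
    "discovered_groups",
    "evaluate",
    "fit_pipeline",
    "generate",
    "load_bundle",
    "load_dataset",
    "majority_label",
    "partition",
    "planted_confusion_sets",
    "run_sweep",
    "save_bundle",
    "train_flat",
    "train_hierarchical",
    "write_dataset",
]
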