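import numpy as np
import pytest

from clusthar import (
    ActivityConfusionMatrix,
    LabeledDataset,
    benchmark_confusion_matrix,
)

SIX_ACTIVITIES = (
    "walking",
    "go-upstairs",
    "go-downstairs",
    "sitting",
    "standing",
    "lying",
)


@pytest.fixture(scope="session")
def benchmark_cm() -> ActivityConfusionMatrix:
    """Packaged six-activity confusion matrix from the smartphone benchmark."""
    return benchmark_confusion_matrix()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_labeled_dataset(
    rng: np.random.Generator,
    n_samples: int = 60,
    n_features: int = 4,
    n_classes: int = 3,
) -> LabeledDataset:
    """Unstructured random dataset for oracle/property tests."""
    labels_pool = [f"act{i}" for i in range(n_classes)]
    labels = rng.choice(labels_pool, size=n_samples)
    # guarantee every class appears
    labels[:n_classes] = labels_pool
    return LabeledDataset(
        rng.normal(size=(n_samples, n_features)),
        labels.astype(object),
        tuple(labels_pool),
    )


def blob_dataset(
    rng: np.random.Generator,
    centers: np.ndarray,
    labels: list[str],
    n_per: int = 30,
    spread: float = 0.05,
) -> LabeledDataset:
    """Well-separated Gaussian blobs, one per label."""
    xs, ys = [], []
    for c, lab in zip(centers, labels):
        xs.append(c + spread * rng.standard_normal((n_per, len(c))))
        ys.extend([lab] * n_per)
    return LabeledDataset(np.vstack(xs), np.array(ys, dtype=object), tuple(labels))
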