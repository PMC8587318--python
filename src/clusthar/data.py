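"""Labeled feature-table container and file loaders.

A dataset is a real-valued sample-by-feature matrix with one activity label
per row. Labels are carried as strings internally; integer activity codes
exist only at the smartphone-dataset file boundary, where they are mapped
through an explicit key.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError

#: Activity key of the six-activity smartphone benchmark layout.
UCIHAR_ACTIVITY_KEY: dict[int, str] = {
    1: "walking",
    2: "go-upstairs",
    3: "go-downstairs",
    4: "sitting",
    5: "standing",
    6: "lying",
}


@dataclass(frozen=True)
class LabeledDataset:
    """Feature matrix ``X`` with per-row activity labels ``Y``.

    Parameters
    ----------
    features:
        Two-dimensional float array, one row per windowed sensor sample.
    labels:
        One activity name per row.
    label_set:
        Ordered list of the distinct activities; every label must be a
        member. The order is load-bearing: it fixes matrix row/column
        order and majority-vote tie-breaking downstream.
    """

    features: np.ndarray
    labels: np.ndarray
    label_set: tuple[str, ...]
    feature_names: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        feats = np.asarray(self.features, dtype=float)
        labs = np.asarray(self.labels, dtype=object)
        if feats.ndim != 2:
            raise ConsistencyError("features must be a 2-D sample×feature matrix")
        if feats.shape[0] != labs.shape[0]:
            raise ConsistencyError(
                f"{feats.shape[0]} feature rows but {labs.shape[0]} labels"
            )
        lset = tuple(self.label_set)
        if len(lset) != len(set(lset)):
            raise ConsistencyError("label_set contains duplicates")
        unknown = set(labs) - set(lset)
        if unknown:
            raise ConsistencyError(f"labels not in label_set: {sorted(unknown)}")
        object.__setattr__(self, "features", feats)
        object.__setattr__(self, "labels", labs)
        object.__setattr__(self, "label_set", lset)
        if self.feature_names is not None:
            names = tuple(self.feature_names)
            if len(names) != feats.shape[1]:
                raise ConsistencyError(
                    f"{len(names)} feature names for {feats.shape[1]} columns"
                )
            object.__setattr__(self, "feature_names", names)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> dict[str, int]:
        labs, counts = np.unique(self.labels.astype(str), return_counts=True)
        present = dict(zip(labs, counts))
        return {a: int(present.get(a, 0)) for a in self.label_set}

    def subset_columns(self, columns: Sequence[int]) -> "LabeledDataset":
        cols = list(columns)
        names = (
            tuple(self.feature_names[c] for c in cols)
            if self.feature_names is not None
            else None
        )
        return LabeledDataset(self.features[:, cols], self.labels, self.label_set, names)

    def subset_rows(self, index: np.ndarray) -> "LabeledDataset":
        return LabeledDataset(
            self.features[index], self.labels[index], self.label_set, self.feature_names
        )


@dataclass(frozen=True)
class DatasetLayout:
    """Where a dataset lives on disk and how to parse it.

    ``kind`` is ``"delimited"`` (labels are strings, configurable
    delimiter) or ``"ucihar"`` (whitespace-separated features, integer
    label codes mapped through ``label_key``).
    """

    kind: str
    feature_path: Path
    label_path: Path
    feature_name_path: Path | None = None
    delimiter: str = "\t"
    label_key: Mapping[int, str] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("delimited", "ucihar"):
            raise FormatError(f"unknown layout kind {self.kind!r}")


def load_dataset(layout: DatasetLayout, columns: Sequence[int] | None = None) -> LabeledDataset:
    """Read a feature file plus a label file into a :class:`LabeledDataset`.

    For the ``ucihar`` kind the ordered label set is built from the integer
    key (ascending code order); for ``delimited`` it is the sorted distinct
    labels. ``columns`` optionally subsets feature columns after loading.
    """
    fpath, lpath = Path(layout.feature_path), Path(layout.label_path)
    if layout.kind == "ucihar":
        features = pd.read_csv(fpath, sep=r"\s+", header=None).to_numpy(dtype=float)
        codes = pd.read_csv(lpath, sep=r"\s+", header=None)[0].to_numpy()
        key = dict(layout.label_key or UCIHAR_ACTIVITY_KEY)
        bad = [i for i, c in enumerate(codes) if int(c) not in key]
        if bad:
            raise FormatError(f"unknown label code at line {bad[0] + 1}: {codes[bad[0]]}")
        labels = np.array([key[int(c)] for c in codes], dtype=object)
        label_set = tuple(key[k] for k in sorted(key))
    else:
        features = pd.read_csv(fpath, sep=layout.delimiter, header=None).to_numpy(dtype=float)
        labels = (
            pd.read_csv(lpath, sep=layout.delimiter, header=None)[0].astype(str).to_numpy(dtype=object)
        )
        label_set = tuple(sorted(set(labels)))
    if features.shape[0] != labels.shape[0]:
        raise FormatError(
            f"feature rows ({features.shape[0]}) != label rows ({labels.shape[0]})"
        )
    names = None
    if layout.feature_name_path is not None:
        raw = Path(layout.feature_name_path).read_text().split()
        # the ucihar names file is "<index> <name>" per line
        if layout.kind == "ucihar" and len(raw) == 2 * features.shape[1]:
            names = tuple(raw[1::2])
        else:
            names = tuple(raw)
    ds = LabeledDataset(features, labels, label_set, names)
    if columns is not None:
        ds = ds.subset_columns(columns)
    return ds


def write_dataset(ds: LabeledDataset, feature_path: Path, label_path: Path, delimiter: str = "\t") -> None:
    """Write features and labels as two delimited text files (no headers)."""
    pd.DataFrame(ds.features).to_csv(feature_path, sep=delimiter, header=False, index=False)
    pd.Series(ds.labels.astype(str)).to_csv(label_path, sep=delimiter, header=False, index=False)


def sensor_columns(feature_names: Sequence[str], sensor: str) -> list[int]:
    """Column indices for a sensor subset, selected by feature-name substring.

    ``sensor`` is ``"accelerometer"``, ``"gyroscope"`` or ``"combined"``.
    On the full 561-name benchmark list this yields 348, 211 and 561
    columns respectively (two angle features involve both units and are
    counted under the combined set only).
    """
    if sensor == "combined":
        return list(range(len(feature_names)))
    tag = {"accelerometer": "Acc", "gyroscope": "Gyro"}.get(sensor)
    if tag is None:
        raise FormatError(f"unknown sensor subset {sensor!r}")
    other = "Gyro" if tag == "Acc" else "Acc"
    return [
        i
        for i, n in enumerate(feature_names)
        if tag in n and not (other in n and tag in n)
    ]
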