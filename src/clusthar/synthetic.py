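"""Synthetic activity-feature generator with planted confusion structure.

Emulates the premise that activities with different semantics can produce
similar sensor readings: activities are partitioned into groups (by
default a "dynamic" group walking / go-upstairs / go-downstairs and a
"static" group sitting / standing / lying), class-conditional features are
spherical Gaussians, and the geometry is controlled by two separations
measured in noise-standard-deviation units — a small one between class
means inside a group and a large one between group centres. Clustering
such data mixes classes within a group but rarely across groups, so the
confusing sets a correct analysis discovers are exactly the planted
group memberships (:func:`planted_confusion_sets`).

Mean placement is a deterministic orthogonal-block layout (group centres
and within-group offsets live on scaled standard-basis vectors), so the
geometry does not depend on the seed; only the noise draws do.

The ``xor_pair`` switch plants, for the first two activities of the first
group, a shared high-variance latent along the (1, 1) direction of two
dedicated feature dimensions with the class offset along (1, -1). The two
classes then overlap heavily in every single coordinate — defeating a
diagonal-covariance model like Gaussian naive Bayes — while remaining
linearly separable, which leaves headroom for a second-level margin
classifier to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset
from .errors import InvalidSpecError

DEFAULT_GROUPS: tuple[tuple[str, ...], ...] = (
    ("walking", "go-upstairs", "go-downstairs"),
    ("sitting", "standing", "lying"),
)

#: scale of the shared latent and of the class offset for the xor pair,
#: in noise-s.d. units
_XOR_LATENT_SD = 8.0
_XOR_OFFSET = 4.0


@dataclass(frozen=True)
class SyntheticSpec:
    groups: tuple[tuple[str, ...], ...] = DEFAULT_GROUPS
    n_per_class: int = 300
    dim: int = 8
    within_group_separation: float = 1.0
    between_group_separation: float = 8.0
    noise_sd: float = 1.0
    seed: int = 0
    xor_pair: bool = False
    n_per_class_test: int | None = field(default=None)

    def __post_init__(self) -> None:
        flat = [a for g in self.groups for a in g]
        if not flat or len(flat) != len(set(flat)):
            raise InvalidSpecError("groups must cover each activity exactly once")
        if self.n_per_class < 1 or self.noise_sd <= 0:
            raise InvalidSpecError("n_per_class must be >= 1 and noise_sd > 0")
        if self.within_group_separation < 0 or self.between_group_separation < 0:
            raise InvalidSpecError("separations must be nonnegative")
        need = len(self.groups) + max(len(g) for g in self.groups)
        if self.xor_pair:
            need += 2
        if self.dim < need:
            raise InvalidSpecError(f"dim must be >= {need} for this group layout")
        if self.xor_pair and len(self.groups[0]) < 2:
            raise InvalidSpecError("xor_pair needs at least two activities in the first group")

    @property
    def label_set(self) -> tuple[str, ...]:
        return tuple(a for g in self.groups for a in g)


def _class_means(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Orthogonal-block layout: group g's centre sits on basis vector g,
    class j's within-group offset on basis vector n_groups + j. Scaling a
    simplex of basis vectors by d/sqrt(2) makes all pairwise distances d."""
    g_scale = spec.between_group_separation * spec.noise_sd / np.sqrt(2)
    w_scale = spec.within_group_separation * spec.noise_sd / np.sqrt(2)
    n_groups = len(spec.groups)
    means = {}
    for g, group in enumerate(spec.groups):
        for j, activity in enumerate(group):
            m = np.zeros(spec.dim)
            m[g] = g_scale
            m[n_groups + j] = w_scale
            means[activity] = m
    return means


def _draw(spec: SyntheticSpec, rng: np.random.Generator, n_per_class: int) -> LabeledDataset:
    means = _class_means(spec)
    order = spec.label_set
    xor_classes = spec.groups[0][:2] if spec.xor_pair else ()
    p, q = spec.dim - 2, spec.dim - 1
    xs, ys = [], []
    for a in order:
        x = means[a] + spec.noise_sd * rng.standard_normal((n_per_class, spec.dim))
        if a in xor_classes:
            latent = _XOR_LATENT_SD * spec.noise_sd * rng.standard_normal(n_per_class)
            x[:, p] += latent
            x[:, q] += latent
            # class offset along (1, -1)/sqrt(2), total separation _XOR_OFFSET
            sign = 1.0 if a == xor_classes[0] else -1.0
            d = sign * _XOR_OFFSET * spec.noise_sd / (2 * np.sqrt(2))
            x[:, p] += d
            x[:, q] -= d
        xs.append(x)
        ys.extend([a] * n_per_class)
    return LabeledDataset(np.vstack(xs), np.array(ys, dtype=object), order)


def generate(spec: SyntheticSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Draw independent train and test sets; fixed seed gives identical output."""
    rng = np.random.default_rng(spec.seed)
    train = _draw(spec, rng, spec.n_per_class)
    test = _draw(spec, rng, spec.n_per_class_test or spec.n_per_class)
    return train, test


def planted_confusion_sets(spec: SyntheticSpec) -> dict[str, frozenset]:
    """Ground-truth confusing sets: each activity's groupmates."""
    return {
        a: frozenset(set(g) - {a})
        for g in spec.groups
        for a in g
    }


def class_means(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Planted class means (pre-noise, without the xor-pair latent)."""
    means = _class_means(spec)
    if spec.xor_pair:
        p, q = spec.dim - 2, spec.dim - 1
        for sign, a in zip((1.0, -1.0), spec.groups[0][:2]):
            d = sign * _XOR_OFFSET * spec.noise_sd / (2 * np.sqrt(2))
            means[a] = means[a].copy()
            means[a][p] += d
            means[a][q] -= d
    return means
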