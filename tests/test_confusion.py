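"""Confusion-index construction: majority votes, the activity confusion
matrix against a brute-force tally, ratio normalisation and threshold
behaviour, including the packaged benchmark matrix worked examples."""

import collections

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from clusthar import (
    ActivityConfusionMatrix,
    ClusterPartition,
    LabeledDataset,
    activity_confusion_matrix,
    confusing_sets,
    confusion_ratios,
    discovered_groups,
    majority_label,
)
from clusthar.errors import (
    ConsistencyError,
    EmptyClusterError,
    InvalidThresholdError,
)
from .conftest import random_labeled_dataset

THETA_GRID = (0.005, 0.01, 0.02, 0.03, 0.05, 0.1, 0.5)


def brute_force_cm(dataset, part):
    """Independent per-sample tally: look up each sample's cluster majority
    and increment one cell."""
    order = dataset.label_set
    majority = {}
    for c in range(part.k):
        members = [dataset.labels[i] for i in range(dataset.n_samples)
                   if part.assignment[i] == c]
        if not members:
            continue
        counts = collections.Counter(members)
        best = max(counts.values())
        majority[c] = next(a for a in order if counts.get(a) == best)
    cm = np.zeros((len(order), len(order)), dtype=int)
    idx = {a: i for i, a in enumerate(order)}
    for i in range(dataset.n_samples):
        cm[idx[dataset.labels[i]], idx[majority[part.assignment[i]]]] += 1
    return cm


class TestMajorityLabel:
    def test_pure_cluster(self):
        assert majority_label(["walking"] * 3, ("walking", "lying")) == "walking"

    def test_plain_majority(self):
        order = ("sitting", "lying")
        assert majority_label(["sitting", "sitting", "lying"], order) == "sitting"

    def test_tie_breaks_to_earliest_label(self):
        order = ("standing", "sitting", "lying")
        members = ["sitting", "lying", "sitting", "lying"]
        assert majority_label(members, order) == "sitting"
        # reversed order flips the winner
        assert majority_label(members, ("lying", "sitting")) == "lying"

    def test_empty_cluster_rejected(self):
        with pytest.raises(EmptyClusterError):
            majority_label([], ("a", "b"))


class TestActivityConfusionMatrix:
    def test_pure_clusters_give_diagonal(self, rng):
        ds = random_labeled_dataset(rng, n_samples=30, n_classes=3)
        order = {a: i for i, a in enumerate(ds.label_set)}
        part = ClusterPartition(np.array([order[l] for l in ds.labels]), 3)
        cm = activity_confusion_matrix(ds, part)
        counts = ds.class_counts()
        assert (cm.counts == np.diag([counts[a] for a in ds.label_set])).all()

    def test_two_cluster_worked_example(self):
        ds = LabeledDataset(
            np.zeros((6, 1)),
            np.array(["A", "A", "B", "B", "B", "A"], dtype=object),
            ("A", "B"),
        )
        part = ClusterPartition(np.array([0, 0, 0, 1, 1, 1]), 2)
        cm = activity_confusion_matrix(ds, part)
        np.testing.assert_array_equal(cm.counts, [[2, 1], [1, 2]])

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_brute_force_tally(self, trial):
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(10, 200))
        k = int(rng.integers(1, 8))
        ds = random_labeled_dataset(rng, n_samples=n, n_classes=int(rng.integers(2, 5)))
        assign = rng.integers(0, k, size=n)
        assign[:k] = np.arange(k)  # keep ids contiguous
        part = ClusterPartition(assign, k)
        cm = activity_confusion_matrix(ds, part)
        np.testing.assert_array_equal(cm.counts, brute_force_cm(ds, part))
        # conservation and row sums
        assert cm.total == n
        counts = ds.class_counts()
        assert list(cm.counts.sum(axis=1)) == [counts[a] for a in ds.label_set]

    def test_sample_order_permutation_invariant(self, rng):
        ds = random_labeled_dataset(rng, n_samples=50)
        assign = rng.integers(0, 4, size=50)
        assign[:4] = np.arange(4)
        perm = rng.permutation(50)
        cm1 = activity_confusion_matrix(ds, ClusterPartition(assign, 4))
        cm2 = activity_confusion_matrix(
            ds.subset_rows(perm), ClusterPartition(assign[perm], 4)
        )
        np.testing.assert_array_equal(cm1.counts, cm2.counts)

    def test_partition_size_mismatch(self, rng):
        ds = random_labeled_dataset(rng, n_samples=10)
        with pytest.raises(ConsistencyError):
            activity_confusion_matrix(ds, ClusterPartition(np.zeros(9, dtype=int), 1))


class TestConfusionRatios:
    def test_benchmark_column_arithmetic(self, benchmark_cm):
        eta = confusion_ratios(benchmark_cm).to_frame()
        col = eta["go-upstairs"]
        assert col["walking"] == pytest.approx(629 / 1599)
        assert col["go-downstairs"] == pytest.approx(137 / 1599)

    def test_diagonal_cm_gives_identity_pattern(self):
        cm = ActivityConfusionMatrix(np.diag([5, 7, 9]), ("a", "b", "c"))
        np.testing.assert_allclose(confusion_ratios(cm).ratios, np.eye(3))

    def test_zero_columns_stay_zero(self, benchmark_cm):
        eta = confusion_ratios(benchmark_cm).to_frame()
        assert (eta["walking"] == 0).all()
        assert (eta["sitting"] == 0).all()

    def test_nonzero_columns_sum_to_one(self, benchmark_cm):
        eta = confusion_ratios(benchmark_cm).ratios
        colsum = benchmark_cm.counts.sum(axis=0)
        np.testing.assert_allclose(eta.sum(axis=0)[colsum > 0], 1.0)


class TestConfusingSets:
    def test_benchmark_at_0_03(self, benchmark_cm):
        s = confusing_sets(benchmark_cm, 0.03)
        assert set(s["go-upstairs"]) == {"walking", "go-downstairs"}

    def test_benchmark_at_0_01(self, benchmark_cm):
        s = confusing_sets(benchmark_cm, 0.01)
        assert set(s["standing"]) == {"sitting", "lying"}
        assert s["walking"] == ()
        assert s["sitting"] == ()
        assert s.nonempty() == ("go-upstairs", "go-downstairs", "standing", "lying")

    def test_diagonal_cm_all_empty(self):
        cm = ActivityConfusionMatrix(np.diag([5, 7]), ("a", "b"))
        for theta in (0.001, 0.5, 1.0):
            assert confusing_sets(cm, theta).nonempty() == ()

    def test_threshold_monotonicity_on_grid(self, benchmark_cm):
        maps = [confusing_sets(benchmark_cm, t).as_sets() for t in THETA_GRID]
        for loose, tight in zip(maps, maps[1:]):
            for a in loose:
                assert tight[a] <= loose[a]

    def test_theta_above_max_eta_empties_everything(self, benchmark_cm):
        eta = confusion_ratios(benchmark_cm).ratios.copy()
        np.fill_diagonal(eta, 0)
        assert confusing_sets(benchmark_cm, min(1.0, eta.max() + 1e-9)).nonempty() == ()

    @pytest.mark.parametrize("theta", [0.0, -0.1, 1.2])
    def test_invalid_threshold(self, benchmark_cm, theta):
        with pytest.raises(InvalidThresholdError):
            confusing_sets(benchmark_cm, theta)


class TestBenchmarkFixtureIntegrity:
    def test_entry_sum_is_training_set_size(self, benchmark_cm):
        assert benchmark_cm.total == 7352

    def test_named_entry(self, benchmark_cm):
        frame = benchmark_cm.to_frame()
        assert frame.loc["go-downstairs", "go-upstairs"] == 137

    def test_tsv_round_trip(self, benchmark_cm, tmp_path):
        path = tmp_path / "cm.tsv"
        benchmark_cm.write_tsv(path)
        back = ActivityConfusionMatrix.read_tsv(path)
        assert back == benchmark_cm


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    counts=arrays(np.int64, (4, 4), elements=st.integers(0, 50)),
    theta_pair=st.tuples(
        st.floats(0.01, 1.0, allow_nan=False), st.floats(0.01, 1.0, allow_nan=False)
    ),
)
def test_confusing_sets_properties_hold_for_any_matrix(counts, theta_pair):
    """For arbitrary nonnegative count matrices: ratio columns sum to one
    (or stay zero), no activity confuses itself, and raising theta never
    adds a confuser."""
    cm = ActivityConfusionMatrix(counts, ("a", "b", "c", "d"))
    eta = confusion_ratios(cm).ratios
    colsum = counts.sum(axis=0)
    np.testing.assert_allclose(eta.sum(axis=0)[colsum > 0], 1.0)
    assert (eta[:, colsum == 0] == 0).all()
    lo, hi = sorted(theta_pair)
    loose, tight = (confusing_sets(cm, t) for t in (lo, hi))
    for a in cm.label_order:
        assert a not in loose[a]
        assert set(tight[a]) <= set(loose[a])


def test_discovered_groups_links_transitively(benchmark_cm):
    """At theta = 0.01 the confusion graph splits the six activities into
    the dynamic and static trios, even though the walking and sitting
    columns are all-zero."""
    groups = discovered_groups(confusing_sets(benchmark_cm, 0.01))
    assert groups == frozenset(
        {
            frozenset({"walking", "go-upstairs", "go-downstairs"}),
            frozenset({"sitting", "standing", "lying"}),
        }
    )
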