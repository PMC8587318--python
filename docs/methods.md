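# Methods

## Model

`clusthar` treats inter-activity confusion as a property of the feature
geometry, measurable without a trained classifier. The premise: if two
activities produce similar sensor readings, an unsupervised partition of
the labeled training set will mix their samples in the same clusters.

Formally, for a training set `D = (X, Y)` over the ordered activity set
`L` and a partition of `X` into `k` clusters, each cluster is assigned
the label with the most members (its *majority label*). The *cluster
confusion index* of a cluster named `L_i` counts, for every activity
`L_j`, the members truly labeled `L_j`; summing over all `k` clusters
gives the *activity confusion index* `CM[j, i]`. `CM` is a `|L| × |L|`
nonnegative integer matrix whose entries total the number of clustered
samples and whose row `j` sums to the class count of `L_j`. Diagonal
entries are stored (a majority class contributes to its own column) but
never treated as confusion.

Column-normalising gives the confusion ratio
`eta(j, i) = CM[j, i] / Σ_j CM[j, i]`, the fraction of the samples
"claimed" by activity `i` that really belong to `j`. A column that is
all-zero — the activity was never any cluster's majority — normalises to
zero by convention rather than raising, because such columns occur in
practice (in the packaged benchmark matrix the walking and sitting
columns are all-zero) and simply mean the activity acquires no confusers.

The confusing set of activity `A` at threshold `theta ∈ (0, 1]` is
`S(A) = { B ≠ A : eta(B, A) ≥ theta }`; the comparison is inclusive.
Majority-vote ties break toward the earliest activity in the ordered
label set — the argmax itself is silent on ties and a deterministic rule
is required for reproducibility.

The hierarchical recognizer is two-level, and only two-level: a top-level
classifier over all of `L` (identical in construction to the flat model),
plus, for each `A` with non-empty `S(A)`, a second-level classifier
trained on exactly the training rows whose true label lies in
`{A} ∪ S(A)`, with the full feature vector and no reweighting — the
minimal reading of "distinguish `A` from `S(A)`". Routing at prediction
time: top-level label first; final unless its confusing set is non-empty,
in which case the matching second-level model decides. A singleton
confusing set just yields a binary second-level model. When families
coincide at both levels the full hyperparameter spec is reused verbatim.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` (cluster count) | `|L| + offset`, offset 0 | clusters in the partition; the offset convention expresses sweeps relative to the activity count |
| `theta` | 0.01 | minimum column ratio for confuser status; useful range ~0.01–0.05 |
| clustering algorithm | k-means | also k-medoids, Ward agglomerative |
| metric | euclidean | cosine / correlation via row-(centre-and-)normalisation for k-means, directly as medoid distance for k-medoids |
| k-means/k-medoids restarts | 10 | best-objective restart selection under one seed |
| classifier families | NB, 1-NN (Euclidean), linear SVM (C=1), decision tree (Gini, unlimited depth) | top and second level may differ |
| feature scaling | off | benchmark feature tables are pre-normalised; a z-score switch exists for other data |

Ward linkage is defined only for Euclidean geometry; requesting it with
cosine or correlation raises an error instead of silently substituting.
Empty k-medoids clusters are repaired by reassigning the sample farthest
from its medoid, and the repair is recorded, so the partition always has
exactly `k` groups.

Metrics: accuracy, macro-averaged precision and recall, and F1 computed
as the harmonic mean of macro precision and macro recall (not the mean of
per-class F1 — the two differ). Macro averaging is an explicit assumption
of this package; classes absent from a test fold contribute zero with a
warning.

## Synthetic generator

The generator emulates the core premise — distinct activities with
similar sensor readings — as class-conditional spherical Gaussians whose
means are laid out deterministically in orthogonal coordinate blocks:
group centres on one set of basis vectors, within-group class offsets on
another, scaled so pairwise within-group mean distances equal
`within_group_separation × noise_sd` and group-centre distances equal
`between_group_separation × noise_sd`. Deterministic mean placement keeps
the geometry independent of the seed; only the noise draws vary. Defaults:
two groups of three activities (dynamic walking/go-upstairs/go-downstairs,
static sitting/standing/lying), `within = 1`, `between = 8`,
`noise_sd = 1`, `n_per_class = 300`, `dim = 8` (the smallest round
dimension accommodating the block layout plus the correlated-pair
coordinates). Train and test sets are independent draws from one seeded
stream.

The `xor_pair` switch plants, for the first two activities of the first
group, a shared high-variance latent (8 noise-s.d.) along the `(1, 1)`
direction of two dedicated coordinates, with the class offset (4
noise-s.d.) along `(1, -1)`. Every single coordinate then overlaps
heavily between the pair — defeating a diagonal-covariance model such as
Gaussian naive Bayes — while the pair remains linearly separable, leaving
headroom for a second-level margin classifier. With purely spherical
classes a strong flat classifier is already near the Bayes bound and
routing has nothing to recover; the correlated pair is the minimal
mechanism that reproduces, on synthetic data, the situation where an
NB-SVM pairing beats flat NB.

What the generator does **not** emulate: raw tri-axial waveforms,
windowing, the benchmark's 561-feature extraction chain, heavy-tailed or
subject-correlated noise, class imbalance. Passing recovery tests
therefore show that the confusion analysis finds planted co-cluster
structure under Gaussian overlap, not that it handles every pathology of
real inertial data.

## Recovery criterion

"Recovering the planted groups" is judged on the confusion *graph*: the
connected components of the undirected graph with an edge `{A, B}`
whenever either confusing set names the other activity
(`discovered_groups`). Per-activity set equality is deliberately not the
criterion: with heavily overlapping classes the partition regularly names
two within-group clusters after the same activity, leaving a third
activity's column all-zero and its own set empty even though its
groupmates' sets still link it. The packaged benchmark matrix shows the
same structure (walking's column is all-zero, yet walking appears in the
sets of both other dynamic activities), and the hierarchy one draws from
it still groups walking with the dynamic trio. The component view is the
statement about grouping structure that the method actually supports.

## Numerical and design notes

- All randomness flows from explicit integer seeds; k-means uses seeded
  restarts, k-medoids a seeded Voronoi iteration over a precomputed
  distance matrix (chosen over PAM for its simplicity and adequate
  quality at these problem sizes; ties in assignment and medoid update
  break toward the lowest index so duplicated rows cluster together and
  repeated runs are byte-identical), agglomerative clustering is
  deterministic.
- Cluster-majority ties, label ordering and confusing-set ordering are
  all pinned to the ordered label set, so every artifact (CM, ratios,
  sets) is reproducible byte-for-byte from a config echo.
- Labels are strings everywhere inside the library; integer codes exist
  only at the smartphone-benchmark file boundary.
- `theta = 1.0` on data whose off-diagonal ratios are below 1 produces no
  second-level models, and the hierarchical model then predicts
  identically to the flat model — the flat-equivalence limit used in
  tests.
- Degenerate inputs fail loudly: single-class training sets, empty
  clusters passed to the majority vote, feature-width mismatches at
  prediction, non-finite features, correlation similarity on a
  constant-valued row (the offending row is named).

## Problem sizes

Tests and the acceptance script run entirely on synthetic data and the
packaged benchmark confusion matrix: recovery and improvement experiments
use 20 seeds at 1800 training / 1800 test samples in 8 dimensions; oracle
checks use ≤ 200-sample random datasets. The full pipeline accepts
arbitrarily larger delimited or benchmark-layout tables through the same
interfaces; k-medoids materialises an n×n distance matrix and is the one
component whose memory grows quadratically with sample count.

## Known limitations

- Exactly two levels; the framework is not applied recursively.
- Confusion is measured from hard cluster memberships only; no soft or
  probabilistic assignment, no hold-out-based confusion.
- No automatic selection of `k` or `theta`.
- Headline accuracies on the external six-activity smartphone benchmark
  depend on an averaging convention that cannot be pinned down from the
  published tables alone; the pipeline can run that experiment when the
  data files are supplied, but no test asserts those table values.
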