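# Methods

This note records the models implemented by dfnckit, the defaults and why
they were chosen, and what the synthetic validation does and does not
establish.

## Windowed connectivity

Connectivity is the Pearson correlation of two component time courses
within a sliding window. The window is tapered: a rectangle of `length`
samples convolved with a unit-area Gaussian of standard deviation
`taper_sigma` samples, truncated to the window and rescaled to a peak of
one. Tapering is applied as a *weighted* correlation — weighted means,
weighted covariance, weighted variances — rather than by pre-multiplying
the signals, so with uniform weights the estimator reduces exactly to the
classical sample correlation coefficient, and the taper down-weights
window edges without biasing the location of the estimate.

Defaults: `length=30` samples, `step=1`, `taper_sigma=3`. These follow
the prevailing convention in the sliding-window dFNC literature (window
of roughly 20–40 TR with a gently tapered edge); all three are
configurable, and no claim is made that any particular published analysis
used exactly these values. Correlations are clipped to [−1, 1] against
rounding. A window in which some component is constant has no defined
correlation; this raises an error naming the subject, window and
component rather than emitting NaN, because a silent NaN would poison
every downstream k-means distance. An optional Fisher z-transform
(arctanh) of the correlations is off by default.

Feature order is the row-major strict upper triangle (pairs i<j) of the
C×C matrix; the mapping is stored explicitly in each tensor's
`feature_index` so containers are self-describing.

## K-means

Lloyd's algorithm with k-means++ seeding, best of `n_init=10` restarts by
the within-cluster sum of squares, `max_iter=300`, and convergence when
assignments stop changing or the relative objective improvement falls
below `tol=1e-4`. All randomness flows from a single integer seed through
spawned child generators, so results are bit-reproducible. Assignment
ties break to the lowest centroid index. An emptied cluster is re-seeded
at the point farthest from its own centroid — moving an unused centroid
cannot increase the objective, so the within-restart objective trace
stays non-increasing.

Squared Euclidean distance is the default, matching the sum-of-squares
objective; city-block distance with median centroid updates is available
because part of the dFNC toolchain uses it. Rows can carry nonnegative
`sample_weight`s (weighted seeding probabilities, updates and objective),
equivalent to replicating rows for integer weights.

## Elbow model-order selection

The model order is chosen from the k-means criterion curve over a k
range. Three selection rules are provided:

- `curvature` (default): the k with the largest second difference of
  log-inertia. On the log scale this measures where the *decay rate* of
  the criterion collapses — the point past which an extra cluster stops
  paying for itself — and is invariant to the criterion's overall
  magnitude, so the large absolute drops at small k do not dominate.
- `chord_distance`: normalize the (k, inertia) points to the unit square
  and take the k farthest from the chord joining the curve's endpoints.
- `wcss_ratio`: the chord construction applied to the within- to
  between-cluster sum-of-squares ratio.

Both geometric constructions are blind at the ends of the curve they see
(endpoints have zero chord distance; the second difference needs both
neighbours), so the inertia curve is anchored with an extra fit at
`k_min − 1` (down to k=1, whose inertia is the total scatter in closed
form) and, for the curvature rule, at `k_max + 1` when the sample size
allows. Anchors participate in the geometry but are never selected.

The curvature rule is the default because, in validation on the
synthetic two-state cohort, the chord rule is unstable on the aggregated-
centroid curve of the two-step pipeline — its top-two candidates differ
by under 2% of the normalized distance, and the selection flips between
the planted order and one above it across seeds — while the curvature
rule recovers the planted order on both pipelines for every seed tested,
with a 25–35% margin between the top candidates.

## The two-step pipeline

Batches are disjoint and exhaust the cohort; when n mod m ≠ 0 the
remainder subjects are appended to the final batch rather than dropped.
Within a batch, windows are pooled across the batch's subjects and
clustered once per k = 2..L, contributing L(L+1)/2 − 1 centroids. The
batch size m may be given as a fraction of the cohort. Data access is
batch-at-a-time through a small source protocol (an in-memory list or a
lazy HDF5 container), so peak residency is one batch during the sweep and
one subject during assignment — the point of the method.

In the second step each aggregated centroid is, by default, weighted by
its source-cluster size. A centroid annotated with its mass is a
sufficient summary of its cluster for the sum-of-squares objective, so
the weighted surrogate tracks the full-data k-means far more closely than
treating every centroid as one observation: on the synthetic cohort the
minimum matched-state correlation against the conventional pipeline is
0.997–0.9998 per seed with weighting versus 0.982–0.997 without. The
unweighted variant (each centroid counted once) remains available
(`weight_second_step=False`, `--unweighted-second-step`).

Final states are renumbered by descending total occupancy across
subjects, so state 0 is always the most visited and numbering is
comparable across runs and pipelines. The conventional baseline pools
every subject's windows, applies the same elbow selection, clusters the
pooled windows directly, and uses the same renumbering.

Default elbow search range is (2, 10); the desk-scale validation uses
(2, 8).

## Temporal features and quality

Occupancy rate is the fraction of a subject's windows in each state
(reported as fractions summing to one; percentages are presentation).
The transition count is the number of adjacent-window label changes.
Mean dwell time is deliberately not computed.

Clustering quality per subject is the distance ratio: for each window,
the sum of Euclidean distances to the centroids of the other K_opt − 1
states divided by the distance to its own state's centroid, averaged over
windows. Higher is crisper. Because the numerator sums K_opt − 1 terms,
ratios are comparable only between models of equal K_opt. Own-state
distances below 1e-12 are floored and logged. Model-to-model similarity
matches states by solving the assignment problem that maximizes summed
Pearson correlation between centroid vectors (exhaustively verifiable for
K ≤ 4); feature similarity across pipelines is the plain Pearson
correlation of per-subject values; quality distributions are compared
with Welch's two-sample t-test (pooled variance available by flag, chosen
because the unequal-variance form needs no additional assumption where
the method's text specifies only "two-sample t-test"-style comparison).

## Synthetic cohort

The generator draws each subject's component time courses from a small
set of multivariate-normal states whose correlation matrices are the
ground-truth connectivity patterns, switching according to a Markov chain
in which every entered state persists at least `min_dwell` samples before
transitions are drawn (run lengths are therefore `min_dwell` plus a
geometric number of extra stays). One child generator per subject makes
the whole cohort bit-reproducible from one seed.

The default cohort: 20 subjects, C=10 components, T=400 timepoints, two
states — state A with one five-component block at r=0.6, state B with the
complementary block at r=0.6 and the two blocks anti-correlated at
r=−0.3 (uniform *within*-block anti-correlation of −0.3 in a
five-component block would not be positive definite, so the negative
structure lives between the blocks) — a symmetric chain with
stay-probability 0.98, and `min_dwell=40`, which exceeds the 30-sample
window so most windows are state-pure. The vectorized planted states
correlate at 0.05, i.e. the states are well separated. These sizes keep a
full five-seed, three-pipeline validation within a couple of minutes on
one core.

What this cohort does *not* emulate: hemodynamic autocorrelation within a
state (rows are independent draws), gradual state transitions, subject-
level variability in the state patterns themselves, scanner noise and
motion artefacts, and realistic component counts (C=10, not ~50). Passing
the validation therefore shows the pipeline machinery is correct and that
two-step aggregation preserves well-separated states; it does not show
that any particular empirical dataset has two states or that the defaults
are optimal for real fMRI.

## Known limitations

- Transition counts are small integers; on a 20-subject cohort a single
  boundary "flicker" (one subject gaining or losing two transitions in
  one pipeline) caps the cross-pipeline transition correlation near 0.93
  for that draw, however close the centroids are. The per-subject
  occupancy and centroid agreement are the stable equivalence measures at
  this scale; transition-count correlation stabilizes only as the cohort
  grows.
- The elbow anchors make k_min and (for curvature) k_max selectable, but
  `wcss_ratio` cannot anchor below k=2 (the between-cluster scatter at
  k=1 is zero), so its chord can never return k_min.
- The distance-ratio metric grows with K_opt − 1 by construction; never
  compare it across model orders.
- Wall-clock timings are logged per stage but never asserted or reported
  as results; they are hardware-dependent.
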