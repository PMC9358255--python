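"""K-means optimizer and elbow criterion, checked against independent
oracles (exhaustive partition enumeration, scikit-learn)."""

import itertools

import numpy as np
import pytest
from sklearn.cluster import KMeans as SKKMeans

from dfnckit import (
    ValidationError,
    chord_elbow,
    curvature_elbow,
    elbow_select,
    kmeans_fit,
    match_states,
)


def brute_force_kmeans(X: np.ndarray, k: int) -> float:
    """Oracle: optimal within-cluster sum of squares by enumerating every
    assignment of N points to k clusters."""
    best = np.inf
    n = X.shape[0]
    for labels in itertools.product(range(k), repeat=n):
        labels = np.asarray(labels)
        inertia = 0.0
        for j in range(k):
            pts = X[labels == j]
            if len(pts):
                inertia += ((pts - pts.mean(axis=0)) ** 2).sum()
        best = min(best, inertia)
    return best


def three_blobs(rng, n_per=30, spread=0.05):
    centers = np.array([[0.0, 0.0], [5.0, 5.0], [-5.0, 5.0]])
    return np.vstack(
        [c + spread * rng.standard_normal((n_per, 2)) for c in centers]
    )


class TestKMeansFit:
    def test_zero_dispersion_optimum(self):
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        X = np.repeat(pts, 5, axis=0)
        res = kmeans_fit(X, 3, seed=0)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)
        matched = match_states(res.centroids, pts)
        assert len(matched.pairs) == 3

    def test_two_cluster_1d_exact_solution(self):
        X = np.array([[0.0], [1.0], [9.0], [10.0]])
        res = kmeans_fit(X, 2, seed=0, n_init=10)
        assert res.inertia == pytest.approx(1.0)
        np.testing.assert_allclose(sorted(res.centroids.ravel()), [0.5, 9.5])
        assert res.inertia == pytest.approx(brute_force_kmeans(X, 2))

    def test_k1_closed_form(self, rng):
        X = rng.standard_normal((25, 4))
        res = kmeans_fit(X, 1, seed=3)
        np.testing.assert_allclose(res.centroids[0], X.mean(axis=0))
        assert res.inertia == pytest.approx(((X - X.mean(axis=0)) ** 2).sum())

    @pytest.mark.parametrize("n,k,case", [(8, 3, 0), (10, 2, 1), (7, 3, 2)])
    def test_matches_exhaustive_partition_optimum(self, n, k, case):
        rng = np.random.default_rng(100 + case)
        X = rng.standard_normal((n, 2))
        res = kmeans_fit(X, k, seed=0, n_init=50)
        assert res.inertia == pytest.approx(brute_force_kmeans(X, k), rel=1e-9)

    def test_lloyd_inertia_monotone_within_restart(self, rng):
        X = rng.standard_normal((200, 5))
        res = kmeans_fit(X, 4, seed=2, n_init=1, tol=0.0)
        assert np.all(np.diff(res.inertia_history) <= 1e-7)

    def test_labels_satisfy_nearest_centroid_and_inertia_identity(self, rng):
        X = rng.standard_normal((80, 3))
        res = kmeans_fit(X, 5, seed=8)
        d = ((X[:, None, :] - res.centroids[None]) ** 2).sum(axis=2)
        own = d[np.arange(80), res.labels]
        assert np.all(own <= d.min(axis=1) + 1e-9)
        assert res.inertia == pytest.approx(own.sum(), rel=1e-6)

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((60, 4))
        a = kmeans_fit(X, 3, seed=5)
        b = kmeans_fit(X, 3, seed=5)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        assert a.inertia == b.inertia

    def test_row_permutation_equivariance(self, rng):
        X = three_blobs(rng)
        perm = rng.permutation(X.shape[0])
        a = kmeans_fit(X, 3, seed=1)
        b = kmeans_fit(X[perm], 3, seed=4)
        # both reach the (unique) optimum on well-separated blobs
        assert a.inertia == pytest.approx(b.inertia, rel=1e-9)
        remap = {}
        for j, c in enumerate(b.centroids):
            remap[j] = int(np.argmin(((a.centroids - c) ** 2).sum(axis=1)))
        np.testing.assert_array_equal(
            a.labels[perm], np.array([remap[l] for l in b.labels])
        )

    def test_agreement_with_sklearn(self, rng):
        """Independent cross-check: same objective value as scikit-learn's
        optimizer on moderately separated data."""
        X = np.vstack(
            [rng.standard_normal((60, 6)) + off for off in (0.0, 3.0, 6.0)]
        )
        ours = kmeans_fit(X, 3, seed=0, n_init=10)
        sk = SKKMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert ours.inertia == pytest.approx(sk.inertia_, rel=1e-6)

    def test_sample_weight_equivalent_to_replication(self, rng):
        X = rng.standard_normal((12, 2))
        w = rng.integers(1, 4, size=12).astype(float)
        rep = np.repeat(X, w.astype(int), axis=0)
        a = kmeans_fit(X, 2, seed=0, n_init=30, sample_weight=w)
        b = kmeans_fit(rep, 2, seed=0, n_init=30)
        assert a.inertia == pytest.approx(b.inertia, rel=1e-9)

    def test_validation_errors(self, rng):
        with pytest.raises(ValidationError):
            kmeans_fit(rng.standard_normal((3, 2)), 4)
        bad = rng.standard_normal((5, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValidationError):
            kmeans_fit(bad, 2)

    def test_cityblock_metric_uses_median(self):
        X = np.array([[0.0], [1.0], [5.0], [100.0]])
        res = kmeans_fit(X, 1, seed=0, metric="cityblock")
        assert res.centroids[0, 0] == pytest.approx(np.median(X))


class TestElbow:
    def test_chord_hand_geometry_example(self):
        assert chord_elbow(np.arange(2, 7), [100, 20, 18, 17, 16]) == 3

    def test_chord_requires_three_points(self):
        with pytest.raises(ValidationError):
            chord_elbow([2, 3], [10, 5])

    def test_curvature_hand_example(self):
        # decay rate collapses after k=3
        assert curvature_elbow(np.arange(1, 7), [1000, 300, 90, 80, 72, 65]) == 3

    def test_three_planted_masses_selects_three(self, rng):
        X = three_blobs(rng)
        for method in ("curvature", "chord_distance", "wcss_ratio"):
            curve = elbow_select(X, 2, 6, seed=0, method=method)
            assert curve.selected_k == 3, method

    def test_inertia_curve_nonincreasing(self, rng):
        X = rng.standard_normal((120, 4))
        curve = elbow_select(X, 2, 6, seed=0, method="chord_distance")
        assert np.all(np.diff(curve.criterion) <= 1e-6 * curve.criterion[0])

    def test_selected_k_within_requested_range(self, rng):
        X = three_blobs(rng)
        curve = elbow_select(X, 2, 6, seed=0)
        assert 2 <= curve.selected_k <= 6
        # anchors may extend the fitted curve beyond the range
        assert curve.k_values[0] == 1

    def test_narrow_range_rejected(self, rng):
        with pytest.raises(ValidationError):
            elbow_select(rng.standard_normal((30, 2)), 2, 3, seed=0)

    def test_two_planted_masses_selects_two(self, rng):
        X = np.vstack(
            [
                0.1 * rng.standard_normal((40, 3)),
                [4.0, 0.0, 0.0] + 0.1 * rng.standard_normal((40, 3)),
            ]
        )
        curve = elbow_select(X, 2, 6, seed=0)
        assert curve.selected_k == 2
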