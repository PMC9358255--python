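"""Distance-ratio quality, state matching and cross-pipeline comparison."""

import itertools
import logging

import numpy as np
import pytest

from dfnckit import (
    DFNCTensor,
    DegenerateDataError,
    StateVector,
    ValidationError,
    compare_quality,
    distance_ratio,
    feature_similarity,
    match_states,
    windowed_correlation,
)
from tests.test_pipeline import make_model


def make_1d_tensor(values, subject_id="s"):
    data = np.asarray(values, dtype=np.float64)[:, None]
    return DFNCTensor(
        subject_id, data, np.arange(data.shape[0]), np.array([[0, 1]])
    )


class TestDistanceRatio:
    def test_hand_arithmetic_1d_toy(self):
        model = make_model([[0.0], [10.0]])
        tensor = make_1d_tensor([1.0, 9.0])
        sv = StateVector("s", np.array([0, 1]))
        report = distance_ratio(tensor, model, sv)
        np.testing.assert_allclose(report.per_window_ratios, [9.0, 9.0])
        assert report.r_p == pytest.approx(9.0)

    def test_degenerate_denominator_floored_and_logged(self, caplog):
        model = make_model([[0.0], [5.0]])
        tensor = make_1d_tensor([0.0])
        sv = StateVector("s", np.array([0]))
        with caplog.at_level(logging.WARNING, logger="dfnckit.quality"):
            report = distance_ratio(tensor, model, sv)
        assert report.per_window_ratios[0] == pytest.approx(5.0 / 1e-12)
        assert any("floored" in rec.message for rec in caplog.records)

    def test_matches_brute_force_double_loop(self, rng):
        k, f, t = 4, 6, 30
        centroids = rng.standard_normal((k, f))
        model = make_model(centroids)
        data = rng.standard_normal((t, f))
        tensor = DFNCTensor("s", data, np.arange(t), np.array([[0, i + 1] for i in range(f)]))
        labels = rng.integers(0, k, size=t)
        report = distance_ratio(tensor, model, StateVector("s", labels))
        ratios = []
        for i in range(t):
            d_own = np.sqrt(((data[i] - centroids[labels[i]]) ** 2).sum())
            d_others = sum(
                np.sqrt(((data[i] - centroids[j]) ** 2).sum())
                for j in range(k)
                if j != labels[i]
            )
            ratios.append(d_others / d_own)
        assert report.r_p == pytest.approx(np.mean(ratios), rel=1e-12)
        np.testing.assert_allclose(report.per_window_ratios, ratios)

    def test_increases_when_other_centroids_move_away(self):
        tensor = make_1d_tensor([1.0, 9.0])
        sv = StateVector("s", np.array([0, 1]))
        near = distance_ratio(tensor, make_model([[0.0], [10.0]]), sv).r_p
        far = distance_ratio(tensor, make_model([[0.0], [30.0]]), sv).r_p
        # own assignments unchanged; only the non-own distances grow
        assert far > near

    def test_relabeling_invariance_of_ratio(self, rng):
        centroids = rng.standard_normal((3, 4))
        data = rng.standard_normal((10, 4))
        tensor = DFNCTensor("s", data, np.arange(10), np.array([[0, 1], [0, 2], [0, 3], [1, 2]]))
        labels = rng.integers(0, 3, size=10)
        base = distance_ratio(tensor, make_model(centroids), StateVector("s", labels))
        perm = np.array([2, 0, 1])
        permuted_model = make_model(centroids[np.argsort(perm)])
        report = distance_ratio(
            tensor, permuted_model, StateVector("s", perm[labels])
        )
        assert report.r_p == pytest.approx(base.r_p, rel=1e-12)

    def test_single_state_rejected(self):
        with pytest.raises(ValidationError):
            distance_ratio(
                make_1d_tensor([1.0]),
                make_model([[0.0]]),
                StateVector("s", np.array([0])),
            )


class TestMatchStates:
    def test_identical_sets_identity_pairing(self, rng):
        c = rng.standard_normal((4, 10))
        matching = match_states(c, c)
        assert matching.pairs == [(i, i) for i in range(4)]
        np.testing.assert_allclose(matching.correlations, 1.0)

    def test_row_permutation_recovered(self, rng):
        c = rng.standard_normal((4, 10))
        perm = np.array([2, 0, 3, 1])
        matching = match_states(c, c[perm])
        assert matching.min_correlation == pytest.approx(1.0)
        recovered = dict(matching.pairs)
        for b_idx, a_idx in enumerate(perm):
            assert recovered[a_idx] == b_idx

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_objective_matches_exhaustive_enumeration(self, k, rng):
        a = rng.standard_normal((k, 8))
        b = a + 0.3 * rng.standard_normal((k, 8))
        matching = match_states(a, b)
        corr = np.array(
            [
                [windowed_correlation(x, y, np.ones(8)) for y in b]
                for x in a
            ]
        )
        best = max(
            sum(corr[i, p[i]] for i in range(k))
            for p in itertools.permutations(range(k))
        )
        assert matching.correlations.sum() == pytest.approx(best, abs=1e-9)

    def test_surplus_states_reported(self, rng):
        a = rng.standard_normal((4, 6))
        matching = match_states(a, a[:2])
        assert len(matching.pairs) == 2
        assert len(matching.unmatched_a) == 2
        assert matching.unmatched_b == []

    def test_feature_width_mismatch(self, rng):
        with pytest.raises(ValidationError):
            match_states(rng.standard_normal((2, 5)), rng.standard_normal((2, 6)))


class TestFeatureSimilarity:
    def test_identity_and_sign_flip(self, rng):
        v = rng.standard_normal(12)
        assert feature_similarity(v, v) == pytest.approx(1.0)
        assert feature_similarity(v, -v) == pytest.approx(-1.0)

    def test_matches_unit_weight_windowed_correlation(self, rng):
        a = rng.standard_normal(9)
        b = rng.standard_normal(9)
        assert feature_similarity(a, b) == pytest.approx(
            windowed_correlation(a, b, np.ones(9)), abs=1e-12
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateDataError):
            feature_similarity([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])


class TestCompareQuality:
    def test_identical_groups(self, rng):
        v = rng.standard_normal(10)
        result = compare_quality(v, v)
        assert result.t_statistic == pytest.approx(0.0, abs=1e-12)
        assert result.p_value == pytest.approx(1.0)
        assert result.direction == "equal"

    def test_constant_shift_matches_pooled_formula(self, rng):
        b = rng.standard_normal(15)
        shift = 0.8
        a = b + shift
        result = compare_quality(a, b, equal_var=True)
        s_p = np.sqrt(((a - a.mean()) ** 2).sum() / 14)  # equal variances
        expected_t = shift / (s_p * np.sqrt(2 / 15))
        assert result.t_statistic == pytest.approx(expected_t, rel=1e-10)
        assert result.direction == "A>B"

    def test_group_size_validation(self):
        with pytest.raises(ValidationError):
            compare_quality([1.0], [1.0, 2.0])
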