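"""Clustering quality and cross-pipeline comparison.

Quality of a state assignment is quantified per subject by the distance
ratio: for each window, the sum of Euclidean distances to the centroids
of the *other* states divided by the distance to the window's own state
centroid, averaged over the subject's windows.  A higher ratio means
windows sit closer to their own state relative to the alternatives.
Because the numerator sums over K_opt - 1 centroids, ratios are only
comparable between models with the same K_opt.

Two state models are compared by optimally matching their centroids (an
assignment problem maximizing summed Pearson correlation) and reporting
the per-pair correlations; per-subject feature vectors from two pipelines
are compared by plain Pearson correlation; quality distributions are
compared with a two-sample t-test (Welch by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .exceptions import DegenerateDataError, ValidationError
from .pipeline import StateModel, StateVector
from .windows import DFNCTensor

__all__ = [
    "QualityReport",
    "StateMatching",
    "QualityComparison",
    "distance_ratio",
    "match_states",
    "feature_similarity",
    "compare_quality",
]

logger = logging.getLogger(__name__)

_DENOM_FLOOR = 1e-12


@dataclass
class QualityReport:
    subject_id: str
    r_p: float
    per_window_ratios: np.ndarray


def distance_ratio(
    tensor: DFNCTensor, model: StateModel, sv: StateVector
) -> QualityReport:
    """Per-subject mean distance ratio.

    For window i with own-state distance d_i_c and summed distance to the
    other K_opt - 1 centroids d_i_sc, the ratio is d_i_sc / d_i_c; R_p is
    the mean over the subject's windows.  Own-state distances below 1e-12
    (a window coinciding with its centroid) are floored and logged.
    """
    if model.k_opt < 2:
        raise ValidationError("distance ratio is undefined for a single state")
    if tensor.n_features != model.centroids.shape[1]:
        raise ValidationError("tensor/model feature-count mismatch")
    if sv.labels.shape[0] != tensor.n_windows:
        raise ValidationError("state vector length does not match the tensor")
    if sv.labels.min() < 0 or sv.labels.max() >= model.k_opt:
        raise ValidationError("state labels outside [0, K_opt)")

    dist = cdist(tensor.data, model.centroids, metric="euclidean")
    own = dist[np.arange(tensor.n_windows), sv.labels]
    others = dist.sum(axis=1) - own
    n_floored = int(np.count_nonzero(own < _DENOM_FLOOR))
    if n_floored:
        logger.warning(
            "subject %s: %d window(s) coincide with their centroid; "
            "own-state distance floored at %g",
            sv.subject_id,
            n_floored,
            _DENOM_FLOOR,
        )
    ratios = others / np.maximum(own, _DENOM_FLOOR)
    return QualityReport(
        subject_id=sv.subject_id, r_p=float(ratios.mean()), per_window_ratios=ratios
    )


@dataclass
class StateMatching:
    """Optimal one-to-one pairing between two centroid sets."""

    pairs: list[tuple[int, int]]
    correlations: np.ndarray
    min_correlation: float
    mean_correlation: float
    unmatched_a: list[int]
    unmatched_b: list[int]


def _row_correlations(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every row of ``a`` and every row of
    ``b``; constant rows get correlation 0 with everything."""
    ac = a - a.mean(axis=1, keepdims=True)
    bc = b - b.mean(axis=1, keepdims=True)
    na = np.linalg.norm(ac, axis=1)
    nb = np.linalg.norm(bc, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (ac @ bc.T) / np.outer(na, nb)
    corr[~np.isfinite(corr)] = 0.0
    return np.clip(corr, -1.0, 1.0)


def match_states(centroids_a: np.ndarray, centroids_b: np.ndarray) -> StateMatching:
    """Match states across two models by optimal assignment.

    Solves the rectangular assignment problem maximizing the summed
    Pearson correlation between paired centroid vectors; surplus states
    of the larger model are reported as unmatched.
    """
    a = np.atleast_2d(np.asarray(centroids_a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(centroids_b, dtype=np.float64))
    if a.shape[1] != b.shape[1]:
        raise ValidationError(
            f"centroid feature counts differ: {a.shape[1]} vs {b.shape[1]}"
        )
    corr = _row_correlations(a, b)
    rows, cols = linear_sum_assignment(-corr)
    pairs = [(int(i), int(j)) for i, j in zip(rows, cols)]
    matched = corr[rows, cols]
    return StateMatching(
        pairs=pairs,
        correlations=matched,
        min_correlation=float(matched.min()),
        mean_correlation=float(matched.mean()),
        unmatched_a=sorted(set(range(a.shape[0])) - set(rows.tolist())),
        unmatched_b=sorted(set(range(b.shape[0])) - set(cols.tolist())),
    )


def feature_similarity(values_a: Sequence[float], values_b: Sequence[float]) -> float:
    """Pearson correlation between two per-subject feature vectors."""
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("feature vectors must be 1-D and equal length")
    if a.size < 3:
        raise ValidationError("need at least 3 subjects")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateDataError("feature vector has zero variance")
    return float(stats.pearsonr(a, b).statistic)


class QualityComparison(NamedTuple):
    t_statistic: float
    p_value: float
    direction: str  # 'A>B', 'B>A' or 'equal' by mean difference
    mean_difference: float


def compare_quality(
    r_p_a: Sequence[float], r_p_b: Sequence[float], equal_var: bool = False
) -> QualityComparison:
    """Two-sample t-test on per-subject distance ratios.

    Welch's unequal-variance form by default; ``equal_var=True`` gives the
    pooled-variance test.  Two-sided p-value.
    """
    a = np.asarray(r_p_a, dtype=np.float64)
    b = np.asarray(r_p_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each group needs at least 2 subjects")
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    diff = float(a.mean() - b.mean())
    direction = "equal" if diff == 0 else ("A>B" if diff > 0 else "B>A")
    return QualityComparison(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        direction=direction,
        mean_difference=diff,
    )
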