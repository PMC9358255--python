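"""K-means optimizer and elbow model-order selection.

Both pipeline variants share this module: Lloyd's algorithm minimizing the
within-cluster sum-of-squares, seeded with k-means++, with best-of-n_init
restarts and deterministic behaviour under a fixed seed.  Model order is
chosen by an elbow criterion on the per-k clustering criterion curve.

Distance is squared Euclidean by default, matching the sum-of-squares
objective; city-block distance (with median centroid updates) is available
as an option because parts of the dFNC literature use it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ValidationError

__all__ = [
    "KMeansResult",
    "ElbowCurve",
    "kmeans_fit",
    "elbow_select",
    "chord_elbow",
    "curvature_elbow",
]


@dataclass
class KMeansResult:
    k: int
    centroids: np.ndarray
    labels: np.ndarray
    inertia: float
    n_iter: int
    seed: int
    inertia_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def _pairwise(X: np.ndarray, C: np.ndarray, metric: str) -> np.ndarray:
    if metric == "sqeuclidean":
        # cdist is accurate enough and branch-free for ties (argmin ->
        # lowest index), so assignment tie-breaking is deterministic
        return cdist(X, C, metric="sqeuclidean")
    if metric == "cityblock":
        return cdist(X, C, metric="cityblock")
    raise ValidationError(f"unknown metric {metric!r}")


def _kmeanspp_init(
    X: np.ndarray,
    k: int,
    rng: np.random.Generator,
    metric: str,
    weights: np.ndarray,
) -> np.ndarray:
    n = X.shape[0]
    centroids = np.empty((k, X.shape[1]))
    centroids[0] = X[rng.choice(n, p=weights / weights.sum())]
    closest = _pairwise(X, centroids[:1], metric)[:, 0]
    for j in range(1, k):
        prob = weights * closest
        total = prob.sum()
        if total <= 0:
            centroids[j] = X[rng.integers(n)]
        else:
            r = rng.random() * total
            idx = int(np.searchsorted(np.cumsum(prob), r))
            centroids[j] = X[min(idx, n - 1)]
        d_new = _pairwise(X, centroids[j : j + 1], metric)[:, 0]
        np.minimum(closest, d_new, out=closest)
    return centroids


def _update_centroids(
    X: np.ndarray,
    labels: np.ndarray,
    k: int,
    metric: str,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    centroids = np.zeros((k, X.shape[1]))
    mass = np.bincount(labels, weights=weights, minlength=k)
    if metric == "cityblock":
        for j in range(k):
            if mass[j]:
                centroids[j] = np.median(X[labels == j], axis=0)
    else:
        np.add.at(centroids, labels, X * weights[:, None])
        nz = mass > 0
        centroids[nz] /= mass[nz, None]
    return centroids, mass


def _lloyd(
    X: np.ndarray,
    init: np.ndarray,
    max_iter: int,
    tol: float,
    metric: str,
    weights: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float, int, list[float]]:
    k = init.shape[0]
    centroids = init.copy()
    prev_labels: np.ndarray | None = None
    prev_inertia = np.inf
    history: list[float] = []
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        dist = _pairwise(X, centroids, metric)
        labels = dist.argmin(axis=1)
        own = dist[np.arange(X.shape[0]), labels]
        inertia = float((weights * own).sum())
        history.append(inertia)
        new_centroids, counts = _update_centroids(X, labels, k, metric, weights)
        # empty-cluster repair: re-seed at the point farthest from its
        # own centroid; moving an unused centroid cannot raise the objective
        empties = np.flatnonzero(counts == 0)
        if empties.size:
            own_work = own.copy()
            for j in empties:
                far = int(own_work.argmax())
                new_centroids[j] = X[far]
                own_work[far] = 0.0
        else:
            if prev_labels is not None and np.array_equal(labels, prev_labels):
                centroids = new_centroids
                break
            if np.isfinite(prev_inertia) and (
                prev_inertia - inertia
            ) <= tol * prev_inertia:
                centroids = new_centroids
                break
        centroids = new_centroids
        prev_labels = labels
        prev_inertia = inertia
    # final consistent assignment against the converged centroids
    dist = _pairwise(X, centroids, metric)
    labels = dist.argmin(axis=1)
    inertia = float((weights * dist[np.arange(X.shape[0]), labels]).sum())
    history.append(inertia)
    return centroids, labels, inertia, n_iter, history


def kmeans_fit(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
    metric: str = "sqeuclidean",
    sample_weight: np.ndarray | None = None,
) -> KMeansResult:
    """Fit k-means by Lloyd iterations from k-means++ seeding.

    Runs ``n_init`` restarts (child seeds spawned from ``seed``) and keeps
    the solution with the lowest within-cluster sum of squares (or summed
    city-block distance when ``metric='cityblock'``).  Convergence within
    a restart is declared when assignments stop changing or the relative
    inertia improvement drops below ``tol``.  Deterministic given ``seed``.

    ``sample_weight`` assigns each row a nonnegative multiplicity: the
    objective, centroid updates and k-means++ seeding probabilities all
    weight rows accordingly (equivalent to replicating rows, for integer
    weights).  Only supported with the squared-Euclidean metric.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D (samples x features)")
    if not np.all(np.isfinite(X)):
        raise ValidationError("X contains non-finite values")
    n = X.shape[0]
    if not (n >= k >= 1):
        raise ValidationError(f"need N >= k >= 1, got N={n}, k={k}")
    if n_init < 1:
        raise ValidationError("n_init must be >= 1")
    if sample_weight is None:
        weights = np.ones(n)
    else:
        if metric != "sqeuclidean":
            raise ValidationError("sample_weight requires the sqeuclidean metric")
        weights = np.asarray(sample_weight, dtype=np.float64)
        if weights.shape != (n,) or np.any(weights < 0) or weights.sum() <= 0:
            raise ValidationError(
                "sample_weight must be nonnegative, length N, with positive sum"
            )

    best: KMeansResult | None = None
    for child in np.random.SeedSequence(seed).spawn(n_init):
        rng = np.random.default_rng(child)
        init = _kmeanspp_init(X, k, rng, metric, weights)
        centroids, labels, inertia, n_iter, history = _lloyd(
            X, init, max_iter, tol, metric, weights
        )
        if best is None or inertia < best.inertia:
            best = KMeansResult(
                k=k,
                centroids=centroids,
                labels=labels,
                inertia=inertia,
                n_iter=n_iter,
                seed=seed,
                inertia_history=np.asarray(history),
            )
    assert best is not None
    return best


@dataclass
class ElbowCurve:
    """Per-k clustering criterion with the elbow-selected model order.

    ``method_tag`` is one of ``curvature`` (default), ``chord_distance``
    or ``wcss_ratio``.  ``k_values`` may include anchor points outside the
    requested search range (see :func:`elbow_select`); ``selected_k``
    always lies inside the requested range.
    """

    k_values: np.ndarray
    criterion: np.ndarray
    selected_k: int
    method_tag: str

    def __post_init__(self) -> None:
        self.k_values = np.asarray(self.k_values, dtype=np.int64)
        self.criterion = np.asarray(self.criterion, dtype=np.float64)
        if self.selected_k not in self.k_values:
            raise ValidationError("selected_k must be one of k_values")


def chord_elbow(
    k_values: np.ndarray,
    criterion: np.ndarray,
    select_min: int | None = None,
    select_max: int | None = None,
) -> int:
    """Geometric elbow: the k whose normalized (k, criterion) point lies
    farthest (perpendicular) from the chord joining the curve's endpoints.

    Points are normalized to the unit square first.  Endpoints have zero
    chord distance, so the elbow is always interior to ``k_values``; an
    optional [select_min, select_max] restriction limits the candidates.
    Ties break toward the smaller k.
    """
    k_values = np.asarray(k_values, dtype=np.float64)
    criterion = np.asarray(criterion, dtype=np.float64)
    if k_values.size != criterion.size or k_values.size < 3:
        raise ValidationError("chord elbow needs >= 3 (k, criterion) points")
    if np.any(np.diff(k_values) <= 0):
        raise ValidationError("k_values must be strictly ascending")

    x = (k_values - k_values[0]) / (k_values[-1] - k_values[0])
    span = criterion.max() - criterion.min()
    y = (criterion - criterion.min()) / (span if span > 0 else 1.0)
    # perpendicular distance from (x, y) to the line through the endpoints
    x0, y0, x1, y1 = x[0], y[0], x[-1], y[-1]
    norm = np.hypot(x1 - x0, y1 - y0)
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0) / norm

    mask = np.ones(k_values.size, dtype=bool)
    if select_min is not None:
        mask &= k_values >= select_min
    if select_max is not None:
        mask &= k_values <= select_max
    if not mask.any():
        raise ValidationError("selection range excludes every candidate k")
    candidates = np.flatnonzero(mask)
    best = candidates[int(np.argmax(dist[candidates]))]
    return int(k_values[best])


def curvature_elbow(
    k_values: np.ndarray,
    criterion: np.ndarray,
    select_min: int | None = None,
    select_max: int | None = None,
) -> int:
    """Elbow as the largest second difference of the log criterion.

    The discrete second difference of log(criterion) at k measures how
    sharply the curve's *decay rate* changes there; the true model order
    is where adding one more cluster stops paying off, which is exactly
    where the relative improvement collapses.  Working on the log scale
    makes the rule invariant to the criterion's overall magnitude, so
    early large absolute drops do not dominate.  Endpoints of the supplied
    curve are not selectable (the second difference needs both
    neighbours).  Ties break toward the smaller k.
    """
    k_values = np.asarray(k_values, dtype=np.int64)
    criterion = np.asarray(criterion, dtype=np.float64)
    if k_values.size != criterion.size or k_values.size < 3:
        raise ValidationError("curvature elbow needs >= 3 (k, criterion) points")
    if np.any(np.diff(k_values) <= 0):
        raise ValidationError("k_values must be strictly ascending")
    logc = np.log(np.maximum(criterion, 1e-300))
    d2 = logc[:-2] - 2.0 * logc[1:-1] + logc[2:]
    inner = k_values[1:-1]
    mask = np.ones(inner.size, dtype=bool)
    if select_min is not None:
        mask &= inner >= select_min
    if select_max is not None:
        mask &= inner <= select_max
    if not mask.any():
        raise ValidationError("selection range excludes every candidate k")
    candidates = np.flatnonzero(mask)
    best = candidates[int(np.argmax(d2[candidates]))]
    return int(inner[best])


def elbow_select(
    X: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    method: str = "curvature",
    n_init: int = 10,
    max_iter: int = 300,
    tol: float = 1e-4,
    metric: str = "sqeuclidean",
    sample_weight: np.ndarray | None = None,
) -> ElbowCurve:
    """Sweep k over [k_min, k_max] and pick the model order at the elbow.

    ``method='curvature'`` (default) applies :func:`curvature_elbow` to
    the inertia curve; ``method='chord_distance'`` applies
    :func:`chord_elbow` to it; ``method='wcss_ratio'`` applies the chord
    construction to the ratio of within- to between-cluster sum of
    squares, the convention in the dFNC toolchain.  Neither geometric
    construction can select an endpoint of the curve it sees, so the
    inertia curve is anchored with an extra fit at ``k_min - 1`` (down to
    k=1) and — for the curvature rule — at ``k_max + 1`` when the sample
    size allows; anchors participate in the geometry but are never
    selected, keeping the whole requested range reachable.
    """
    X = np.asarray(X, dtype=np.float64)
    if not (k_max >= k_min >= 2):
        raise ValidationError("need k_max >= k_min >= 2")
    if X.shape[0] < k_max:
        raise ValidationError(f"need N >= k_max, got N={X.shape[0]}, k_max={k_max}")
    if method not in ("curvature", "chord_distance", "wcss_ratio"):
        raise ValidationError(f"unknown elbow method {method!r}")
    if k_max - k_min + 1 < 3:
        raise ValidationError("elbow selection needs at least 3 k values")

    # Anchor only the inertia curve: the within/between ratio is undefined
    # at k=1 (zero between-cluster scatter), so the ratio variant sweeps
    # the requested range as-is.
    anchor = k_min - 1 if method in ("curvature", "chord_distance") else k_min
    top = k_max + 1 if (method == "curvature" and X.shape[0] > k_max) else k_max
    ks = np.arange(anchor, top + 1)
    seeds = np.random.SeedSequence(seed).spawn(ks.size)
    inertias = np.empty(ks.size)
    criterion = np.empty(ks.size)
    w = np.ones(X.shape[0]) if sample_weight is None else np.asarray(sample_weight)
    grand_mean = (w[:, None] * X).sum(axis=0) / w.sum()
    total_ss = float((w[:, None] * (X - grand_mean) ** 2).sum())
    for i, (k, child) in enumerate(zip(ks, seeds)):
        res = kmeans_fit(
            X,
            int(k),
            seed=int(child.generate_state(1)[0] % (2**31)),
            n_init=n_init,
            max_iter=max_iter,
            tol=tol,
            metric=metric,
            sample_weight=sample_weight,
        )
        inertias[i] = res.inertia
        if method == "wcss_ratio":
            between = max(total_ss - res.inertia, 1e-12)
            criterion[i] = res.inertia / between
        else:
            criterion[i] = res.inertia
    if method == "curvature":
        selected = curvature_elbow(ks, criterion, select_min=k_min, select_max=k_max)
    else:
        selected = chord_elbow(ks, criterion, select_min=k_min, select_max=k_max)
    return ElbowCurve(
        k_values=ks, criterion=criterion, selected_k=selected, method_tag=method
    )
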