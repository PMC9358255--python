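"""Two-step subsample-and-aggregate state clustering, plus the
conventional single-pass baseline.

The two-step pipeline avoids ever pooling the full window collection:

1. Subjects are partitioned into disjoint batches of ``m``.  Each batch's
   windows are pooled and clustered repeatedly with k = 2..L, and all
   resulting centroids are kept — L(L+1)/2 - 1 rows per batch.
2. The stacked centroids from all batches form a small surrogate dataset;
   the elbow criterion on it selects the model order K_opt.
3. A second k-means at K_opt on the stacked centroids yields the final
   group states.
4. Every subject's windows are assigned to the nearest final state,
   giving per-subject state vectors.

The conventional baseline pools every subject's windows, selects the
order by the same elbow criterion, and clusters the pooled data directly.
Both pipelines reindex their final states by descending group occupancy so
state numbering is comparable across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.spatial.distance import cdist

from .clustering import ElbowCurve, elbow_select, kmeans_fit
from .exceptions import ValidationError
from .windows import DFNCTensor

__all__ = [
    "TwoStepConfig",
    "AggregatedCentroids",
    "StateModel",
    "StateVector",
    "TensorSource",
    "InMemoryTensorSource",
    "partition_subjects",
    "first_step_sweep",
    "run_two_step",
    "run_conventional",
    "assign_states",
]


@runtime_checkable
class TensorSource(Protocol):
    """Batch-at-a-time access to per-subject dFNC tensors.

    The two-step pipeline only ever asks for one batch of subjects at a
    time, so implementations may load lazily (see the HDF5 source in
    :mod:`dfnckit.io`); the full collection need never be resident.
    """

    @property
    def subject_ids(self) -> list[str]: ...

    def get(self, subject_id: str) -> DFNCTensor: ...


class InMemoryTensorSource:
    """Trivial :class:`TensorSource` over a list of tensors."""

    def __init__(self, tensors: Sequence[DFNCTensor]):
        ids = [t.subject_id for t in tensors]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids in tensor list")
        self._by_id = {t.subject_id: t for t in tensors}

    @property
    def subject_ids(self) -> list[str]:
        return list(self._by_id)

    def get(self, subject_id: str) -> DFNCTensor:
        return self._by_id[subject_id]


def _as_source(tensors) -> TensorSource:
    if isinstance(tensors, (list, tuple)):
        return InMemoryTensorSource(tensors)
    return tensors


@dataclass
class TwoStepConfig:
    """Parameters of the two-step run.

    ``m`` is the number of subjects per first-step batch; a float in
    (0, 1) is interpreted as a fraction of the cohort.  ``L`` is the top
    of the first-step k sweep (k = 2..L).  ``k_range`` bounds the elbow
    search for the final model order.  ``weight_second_step`` controls
    whether each aggregated centroid enters the second step weighted by
    its source-cluster size (the default — the weighted centroid set then
    summarizes the full window collection, not just its cluster shapes)
    or as a plain unweighted observation.
    """

    m: int | float = 2
    L: int = 6
    k_range: tuple[int, int] = (2, 10)
    seed: int = 0
    shuffle: bool = True
    elbow_method: str = "curvature"
    n_init: int = 10
    metric: str = "sqeuclidean"
    weight_second_step: bool = True

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValidationError("L must be >= 2")
        if isinstance(self.m, float) and not self.m.is_integer():
            if not (0 < self.m < 1):
                raise ValidationError("fractional m must lie in (0, 1)")
        elif int(self.m) < 1:
            raise ValidationError("m must be >= 1")

    def resolve_m(self, n_subjects: int) -> int:
        if isinstance(self.m, float) and 0 < self.m < 1:
            m = max(1, round(self.m * n_subjects))
        else:
            m = int(self.m)
        if m > n_subjects:
            raise ValidationError(
                f"m={m} exceeds the number of subjects ({n_subjects})"
            )
        return m


@dataclass
class AggregatedCentroids:
    """Stacked first-step centroids with their provenance.

    ``provenance[i] = (batch_index, k_of_origin, within_k_cluster_index)``
    for row ``i``; ``sizes[i]`` is the source cluster's member count (used
    only by the optional size-weighted second step).
    """

    data: np.ndarray
    provenance: np.ndarray
    sizes: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]


@dataclass
class StateModel:
    """Final group states plus the elbow curve that selected the order."""

    k_opt: int
    centroids: np.ndarray
    elbow: ElbowCurve
    pipeline_tag: str
    config: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.centroids)):
            raise ValidationError("state centroids must be finite")
        if self.k_opt != self.elbow.selected_k:
            raise ValidationError("k_opt must equal elbow.selected_k")


@dataclass
class StateVector:
    """Per-subject sequence of state assignments, one label per window."""

    subject_id: str
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)


def partition_subjects(
    subject_ids: Sequence[str],
    m: int,
    seed: int = 0,
    shuffle: bool = True,
) -> list[list[str]]:
    """Split subjects into disjoint batches of ``m``.

    Every subject appears exactly once.  When ``n mod m != 0`` the
    remainder subjects are appended to the final batch rather than
    dropped, so the partition exhausts the cohort.
    """
    ids = list(subject_ids)
    n = len(ids)
    if len(set(ids)) != n:
        raise ValidationError("duplicate subject ids")
    if not (1 <= m <= n):
        raise ValidationError(f"need 1 <= m <= n, got m={m}, n={n}")
    if shuffle:
        rng = np.random.default_rng(seed)
        ids = [ids[i] for i in rng.permutation(n)]
    n_batches = n // m
    batches = [ids[i * m : (i + 1) * m] for i in range(n_batches)]
    if n % m:
        batches[-1].extend(ids[n_batches * m :])
    return batches


def first_step_sweep(
    batches: Iterable[Sequence[DFNCTensor]],
    L: int,
    seed: int = 0,
    n_init: int = 10,
    metric: str = "sqeuclidean",
) -> AggregatedCentroids:
    """Per-batch k sweep: pool each batch's windows, run k-means for every
    k in [2, L], and stack all centroids.

    Each full batch contributes exactly ``L(L+1)/2 - 1`` rows (the sum of
    k over k = 2..L).  ``batches`` may be a generator, in which case only
    one batch's windows are resident at a time.
    """
    if L < 2:
        raise ValidationError("L must be >= 2")
    ss = np.random.SeedSequence(seed)
    rows: list[np.ndarray] = []
    prov: list[tuple[int, int, int]] = []
    sizes: list[int] = []
    for b_idx, batch in enumerate(batches):
        pooled = np.vstack([t.data for t in batch])
        if pooled.shape[0] < L:
            raise ValidationError(
                f"batch {b_idx} has {pooled.shape[0]} pooled windows, "
                f"fewer than L={L}"
            )
        for k, child in zip(range(2, L + 1), ss.spawn(L - 1)):
            res = kmeans_fit(
                pooled,
                k,
                seed=int(child.generate_state(1)[0] % (2**31)),
                n_init=n_init,
                metric=metric,
            )
            rows.append(res.centroids)
            counts = np.bincount(res.labels, minlength=k)
            for j in range(k):
                prov.append((b_idx, k, j))
                sizes.append(int(counts[j]))
    return AggregatedCentroids(
        data=np.vstack(rows),
        provenance=np.asarray(prov, dtype=np.int64),
        sizes=np.asarray(sizes, dtype=np.int64),
    )


def assign_states(model: StateModel, tensor: DFNCTensor) -> StateVector:
    """Label each window with its nearest state centroid (squared
    Euclidean; ties go to the lowest state index)."""
    if tensor.n_features != model.centroids.shape[1]:
        raise ValidationError(
            f"tensor has F={tensor.n_features} features but the model "
            f"expects F={model.centroids.shape[1]}"
        )
    dist = cdist(tensor.data, model.centroids, metric="sqeuclidean")
    return StateVector(subject_id=tensor.subject_id, labels=dist.argmin(axis=1))


def _reindex_by_occupancy(
    centroids: np.ndarray, state_vectors: list[StateVector]
) -> tuple[np.ndarray, list[StateVector]]:
    """Renumber states by descending total occupancy across subjects
    (ties keep the lower original index) so state 0 is always the most
    visited state, comparable across runs and pipelines."""
    k = centroids.shape[0]
    counts = np.zeros(k, dtype=np.int64)
    for sv in state_vectors:
        counts += np.bincount(sv.labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    new_centroids = centroids[order]
    new_svs = [
        StateVector(subject_id=sv.subject_id, labels=remap[sv.labels])
        for sv in state_vectors
    ]
    return new_centroids, new_svs


def _finalize(
    centroids: np.ndarray,
    elbow: ElbowCurve,
    source: TensorSource,
    tag: str,
    config: dict,
) -> tuple[StateModel, list[StateVector]]:
    model = StateModel(
        k_opt=elbow.selected_k,
        centroids=centroids,
        elbow=elbow,
        pipeline_tag=tag,
        config=config,
    )
    svs = [assign_states(model, source.get(sid)) for sid in source.subject_ids]
    model.centroids, svs = _reindex_by_occupancy(model.centroids, svs)
    return model, svs


def run_two_step(
    tensors, config: TwoStepConfig
) -> tuple[StateModel, list[StateVector]]:
    """Run the full two-step pipeline over a tensor collection.

    ``tensors`` may be a list of :class:`DFNCTensor` or any
    :class:`TensorSource` (e.g. the lazy HDF5 source), accessed one batch
    at a time.
    """
    source = _as_source(tensors)
    ids = source.subject_ids
    m = config.resolve_m(len(ids))
    ss = np.random.SeedSequence(config.seed)
    s_part, s_sweep, s_elbow, s_final = (
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)
    )

    batches = partition_subjects(ids, m, seed=s_part, shuffle=config.shuffle)
    agg = first_step_sweep(
        ([source.get(sid) for sid in batch] for batch in batches),
        L=config.L,
        seed=s_sweep,
        n_init=config.n_init,
        metric=config.metric,
    )
    sample_weight = None
    if config.weight_second_step:
        sample_weight = np.maximum(agg.sizes, 1).astype(np.float64)

    elbow = elbow_select(
        agg.data,
        k_min=config.k_range[0],
        k_max=config.k_range[1],
        seed=s_elbow,
        method=config.elbow_method,
        n_init=config.n_init,
        metric=config.metric,
        sample_weight=sample_weight,
    )
    final = kmeans_fit(
        agg.data,
        elbow.selected_k,
        seed=s_final,
        n_init=config.n_init,
        metric=config.metric,
        sample_weight=sample_weight,
    )
    cfg = asdict(config)
    cfg["resolved_m"] = m
    cfg["n_aggregated_centroids"] = int(agg.n_rows)
    return _finalize(final.centroids, elbow, source, "two_step", cfg)


def run_conventional(
    tensors,
    k_range: tuple[int, int] = (2, 10),
    seed: int = 0,
    elbow_method: str = "curvature",
    n_init: int = 10,
    metric: str = "sqeuclidean",
) -> tuple[StateModel, list[StateVector]]:
    """Single-pass baseline: pool every subject's windows, pick the order
    by the elbow criterion, cluster the pooled windows directly."""
    source = _as_source(tensors)
    ids = source.subject_ids
    if not ids:
        raise ValidationError("no subjects")
    pooled_parts = []
    n_features = None
    for sid in ids:
        t = source.get(sid)
        if n_features is None:
            n_features = t.n_features
        elif t.n_features != n_features:
            raise ValidationError(
                f"subject {sid!r} has F={t.n_features}, expected {n_features}"
            )
        pooled_parts.append(t.data)
    pooled = np.vstack(pooled_parts)

    ss = np.random.SeedSequence(seed)
    s_elbow, s_final = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    elbow = elbow_select(
        pooled,
        k_min=k_range[0],
        k_max=k_range[1],
        seed=s_elbow,
        method=elbow_method,
        n_init=n_init,
        metric=metric,
    )
    final = kmeans_fit(
        pooled, elbow.selected_k, seed=s_final, n_init=n_init, metric=metric
    )
    cfg = {"k_range": list(k_range), "seed": seed, "elbow_method": elbow_method}
    return _finalize(final.centroids, elbow, source, "conventional", cfg)
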