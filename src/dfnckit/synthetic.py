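"""Synthetic multi-subject time courses with planted connectivity states.

The generator emulates the statistical structure the state clustering
assumes: each subject's component time courses are drawn from a small set
of multivariate-normal "states", each defined by a correlation matrix, and
the active state switches over time according to a Markov chain with a
minimum dwell time.  Ground-truth timepoint labels and the planted state
centroids (vectorized correlation matrices) are returned alongside the
data so every downstream stage can be validated without external data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .windows import ComponentTimeCourses, WindowSpec, feature_pairs

__all__ = [
    "StateSpec",
    "SimulationConfig",
    "SimulationTruth",
    "generate_state_sequence",
    "generate_timecourses",
    "default_fixture",
    "default_config",
]


@dataclass
class StateSpec:
    """One planted connectivity state.

    ``covariance`` is a C x C symmetric positive-definite matrix; when
    ``correlation_form`` is set the diagonal must be exactly 1 so the
    matrix doubles as the state's correlation structure.
    """

    state_id: int
    covariance: np.ndarray
    mean: np.ndarray | None = None
    correlation_form: bool = True

    def __post_init__(self) -> None:
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        if self.state_id < 0:
            raise ValidationError("state_id must be >= 0")
        cov = self.covariance
        if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
            raise ValidationError(f"state {self.state_id}: covariance must be square")
        if np.abs(cov - cov.T).max() > 1e-10:
            raise ValidationError(f"state {self.state_id}: covariance not symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() <= 0:
            raise ValidationError(
                f"state {self.state_id}: covariance is not positive definite "
                f"(min eigenvalue {eigvals.min():.3e})"
            )
        if self.correlation_form and np.abs(np.diag(cov) - 1.0).max() > 1e-10:
            raise ValidationError(
                f"state {self.state_id}: correlation-form covariance must have "
                "a unit diagonal"
            )
        if self.mean is None:
            self.mean = np.zeros(cov.shape[0])
        else:
            self.mean = np.asarray(self.mean, dtype=np.float64)
            if self.mean.shape != (cov.shape[0],):
                raise ValidationError(f"state {self.state_id}: mean length mismatch")

    @property
    def n_components(self) -> int:
        return self.covariance.shape[0]

    def correlation_vector(self) -> np.ndarray:
        """Vectorized strict upper triangle of the state correlation matrix
        (same feature order as the dFNC tensors)."""
        cov = self.covariance
        d = 1.0 / np.sqrt(np.diag(cov))
        corr = cov * np.outer(d, d)
        i, j = feature_pairs(cov.shape[0]).T
        return corr[i, j]


@dataclass
class SimulationConfig:
    """Full description of one multi-subject simulation."""

    n_subjects: int
    n_components: int
    t_total: int
    states: list[StateSpec]
    transition_matrix: np.ndarray
    min_dwell: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=np.float64)
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if not self.states:
            raise ValidationError("need at least one state")
        k = len(self.states)
        _validate_transition_matrix(self.transition_matrix, k)
        for s in self.states:
            if s.n_components != self.n_components:
                raise ValidationError(
                    f"state {s.state_id}: covariance is "
                    f"{s.n_components}x{s.n_components}, expected "
                    f"{self.n_components}x{self.n_components}"
                )
        if not (self.t_total >= self.min_dwell >= 1):
            raise ValidationError("need t_total >= min_dwell >= 1")

    def warn_if_short_dwell(self, window_length: int) -> None:
        """Windows longer than the minimum dwell straddle state changes;
        recommended (not required) that min_dwell >= window length."""
        if self.min_dwell < window_length:
            warnings.warn(
                f"min_dwell ({self.min_dwell}) is shorter than the window "
                f"length ({window_length}); many windows will mix states",
                stacklevel=2,
            )


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated dataset."""

    timepoint_labels: list[np.ndarray]
    planted_centroids: np.ndarray  # K_true x F
    window_labels: list[np.ndarray] | None = None

    @property
    def n_states(self) -> int:
        return self.planted_centroids.shape[0]

    def fill_window_labels(self, spec: WindowSpec) -> list[np.ndarray]:
        """Window-level ground truth: the majority timepoint label within
        each window, ties broken toward the state entered earlier in the
        window."""
        self.window_labels = [
            window_majority_labels(lab, spec) for lab in self.timepoint_labels
        ]
        return self.window_labels


def window_majority_labels(labels: np.ndarray, spec: WindowSpec) -> np.ndarray:
    labels = np.asarray(labels)
    n_win = spec.n_windows(labels.shape[0])
    out = np.empty(n_win, dtype=np.int64)
    for t in range(n_win):
        s = t * spec.step
        seg = labels[s : s + spec.length]
        vals, first_idx, counts = np.unique(
            seg, return_index=True, return_counts=True
        )
        top = counts == counts.max()
        # among tied majority states, the one appearing earliest wins
        out[t] = vals[top][np.argmin(first_idx[top])]
    return out


def _validate_transition_matrix(mat: np.ndarray, k: int | None = None) -> None:
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValidationError("transition matrix must be square")
    if k is not None and mat.shape[0] != k:
        raise ValidationError(
            f"transition matrix is {mat.shape[0]}x{mat.shape[0]} but there "
            f"are {k} states"
        )
    if np.any(mat < 0) or np.abs(mat.sum(axis=1) - 1.0).max() > 1e-12:
        raise ValidationError("transition matrix rows must be nonnegative and sum to 1")


def generate_state_sequence(
    t_total: int,
    transition_matrix: np.ndarray,
    min_dwell: int = 1,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample a Markov state sequence with a minimum dwell time.

    Each entered state persists for ``min_dwell`` timepoints before the
    chain is consulted again; self-transitions then extend the run one
    timepoint at a time, so run lengths are ``min_dwell`` plus a geometric
    number of extra stays.  The final run may be truncated by ``t_total``.
    The initial state is drawn uniformly.
    """
    transition_matrix = np.asarray(transition_matrix, dtype=np.float64)
    _validate_transition_matrix(transition_matrix)
    if not (t_total >= min_dwell >= 1):
        raise ValidationError("need t_total >= min_dwell >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    k = transition_matrix.shape[0]
    labels = np.empty(t_total, dtype=np.int64)
    state = int(rng.integers(k))
    t = 0
    while t < t_total:
        run_end = min(t + min_dwell, t_total)
        labels[t:run_end] = state
        t = run_end
        while t < t_total:
            nxt = int(rng.choice(k, p=transition_matrix[state]))
            if nxt != state:
                state = nxt
                break
            labels[t] = state
            t += 1
    return labels


def generate_timecourses(
    config: SimulationConfig,
) -> tuple[list[ComponentTimeCourses], SimulationTruth]:
    """Draw the multi-subject dataset described by ``config``.

    Within each constant-label segment, rows are independent draws from
    that state's multivariate normal.  Identical configs (including seed)
    give bit-identical output: one child RNG is spawned per subject from
    the config seed.
    """
    chols = {}
    for s in config.states:
        try:
            chols[s.state_id] = np.linalg.cholesky(s.covariance)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - caught in StateSpec
            raise ValidationError(
                f"state {s.state_id}: covariance is not positive definite"
            ) from exc
    means = {s.state_id: s.mean for s in config.states}
    state_ids = [s.state_id for s in config.states]

    ss = np.random.SeedSequence(config.seed)
    subjects: list[ComponentTimeCourses] = []
    labels_all: list[np.ndarray] = []
    for idx, child in enumerate(ss.spawn(config.n_subjects)):
        rng = np.random.default_rng(child)
        seq_idx = generate_state_sequence(
            config.t_total, config.transition_matrix, config.min_dwell, rng
        )
        labels = np.asarray([state_ids[i] for i in seq_idx], dtype=np.int64)
        data = np.empty((config.t_total, config.n_components))
        # draw segment by segment so each row uses exactly its label's state
        bounds = np.flatnonzero(np.diff(labels)) + 1
        for lo, hi in zip(
            np.concatenate([[0], bounds]), np.concatenate([bounds, [config.t_total]])
        ):
            sid = labels[lo]
            z = rng.standard_normal((hi - lo, config.n_components))
            data[lo:hi] = means[sid] + z @ chols[sid].T
        subjects.append(
            ComponentTimeCourses(subject_id=f"sub-{idx:03d}", data=data)
        )
        labels_all.append(labels)

    centroids = np.vstack([s.correlation_vector() for s in config.states])
    return subjects, SimulationTruth(
        timepoint_labels=labels_all, planted_centroids=centroids
    )


def _block_state_a(n_components: int = 10) -> np.ndarray:
    """State A: one 5-component block correlated at r=0.6, rest uncorrelated."""
    cov = np.eye(n_components)
    half = n_components // 2
    cov[:half, :half] = 0.6
    np.fill_diagonal(cov, 1.0)
    return cov


def _block_state_b(n_components: int = 10) -> np.ndarray:
    """State B: the complementary block correlated at r=0.6, with the two
    blocks anti-correlated at r=-0.3 (within-block anti-correlation at
    -0.3 would not be positive definite for a 5-component block)."""
    cov = np.eye(n_components)
    half = n_components // 2
    cov[half:, half:] = 0.6
    cov[:half, half:] = -0.3
    cov[half:, :half] = -0.3
    np.fill_diagonal(cov, 1.0)
    return cov


def default_config(n_subjects: int = 20, seed: int = 0) -> SimulationConfig:
    """The default two-state study configuration.

    C=10 components, T_total=400 timepoints, two well-separated planted
    states with opposite block structure, a symmetric chain with
    stay-probability 0.98 and a minimum dwell of 40 samples (longer than
    the default 30-sample window, so most windows are state-pure).
    """
    if n_subjects < 2:
        raise ValidationError("default fixture needs n_subjects >= 2")
    states = [
        StateSpec(state_id=0, covariance=_block_state_a()),
        StateSpec(state_id=1, covariance=_block_state_b()),
    ]
    transition = np.array([[0.98, 0.02], [0.02, 0.98]])
    return SimulationConfig(
        n_subjects=n_subjects,
        n_components=10,
        t_total=400,
        states=states,
        transition_matrix=transition,
        min_dwell=40,
        seed=seed,
    )


def default_fixture(
    n_subjects: int = 20, seed: int = 0
) -> tuple[list[ComponentTimeCourses], SimulationTruth]:
    """Generate the default two-state dataset (see :func:`default_config`)."""
    return generate_timecourses(default_config(n_subjects=n_subjects, seed=seed))
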