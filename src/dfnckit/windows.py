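"""Tapered sliding-window connectivity estimation.

Component time courses (one matrix per subject, timepoints x components)
are converted into per-subject dFNC tensors: for every window position the
pairwise Pearson correlation between component signals is computed under a
tapered window, and the strict upper triangle of the resulting C x C
correlation matrix is vectorized into a row of length F = C(C-1)/2.

The taper is a rectangular window convolved with a Gaussian, the prevailing
convention in the sliding-window dFNC literature.  Tapering is implemented
as a *weighted* Pearson correlation; with uniform weights the estimator
reduces exactly to the textbook sample correlation coefficient.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

from .exceptions import DegenerateWindowError, ValidationError

__all__ = [
    "ComponentTimeCourses",
    "WindowSpec",
    "DFNCTensor",
    "taper_weights",
    "windowed_correlation",
    "compute_dfnc_tensor",
]


@dataclass
class ComponentTimeCourses:
    """Per-subject matrix of component activity over time.

    Parameters
    ----------
    subject_id :
        Identifier used in reports and containers.
    data :
        Array of shape ``(T_total, C)``: rows are timepoints, columns are
        components (e.g. ICA-derived intrinsic connectivity networks).
    tr :
        Optional repetition time in seconds; metadata only.
    """

    subject_id: str
    data: np.ndarray
    tr: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValidationError(
                f"time courses for {self.subject_id!r} must be 2-D "
                f"(timepoints x components), got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValidationError(
                f"time courses for {self.subject_id!r} contain non-finite values"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]


def taper_weights(length: int, taper_sigma: float) -> np.ndarray:
    """Taper weights: a rectangle convolved with a unit-area Gaussian.

    The full convolution of a length-``length`` rectangle with a discrete
    Gaussian kernel of standard deviation ``taper_sigma`` (in samples) is
    truncated to its central ``length`` samples and rescaled so the maximum
    weight is 1.  ``taper_sigma=0`` returns the rectangular window.

    Returns a strictly positive, symmetric weight vector of length
    ``length`` with ``max(weights) == 1``.
    """
    length = int(length)
    if length < 2:
        raise ValidationError(f"window length must be >= 2, got {length}")
    if taper_sigma < 0:
        raise ValidationError(f"taper_sigma must be >= 0, got {taper_sigma}")
    if taper_sigma == 0:
        return np.ones(length)
    radius = int(np.ceil(4.0 * taper_sigma))
    offsets = np.arange(-radius, radius + 1, dtype=np.float64)
    kernel = np.exp(-0.5 * (offsets / taper_sigma) ** 2)
    kernel /= kernel.sum()
    full = np.convolve(np.ones(length), kernel)  # length + 2*radius samples
    weights = full[radius : radius + length]
    weights = weights / weights.max()
    return weights


@dataclass
class WindowSpec:
    """Sliding-window parameters.

    length and step are in samples; ``taper_sigma`` is the standard
    deviation (samples) of the Gaussian the rectangle is convolved with
    (0 gives a plain rectangular window).
    """

    length: int = 30
    step: int = 1
    taper_sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValidationError(f"window length must be >= 2, got {self.length}")
        if self.step < 1:
            raise ValidationError(f"window step must be >= 1, got {self.step}")
        if self.taper_sigma < 0:
            raise ValidationError("taper_sigma must be >= 0")

    @cached_property
    def weights(self) -> np.ndarray:
        return taper_weights(self.length, self.taper_sigma)

    def n_windows(self, t_total: int) -> int:
        if t_total < self.length:
            raise ValidationError(
                f"need at least {self.length} timepoints, got {t_total}"
            )
        return (t_total - self.length) // self.step + 1


def _weighted_moments(x: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, float]:
    wsum = weights.sum()
    mean = weights @ x / wsum
    return x - mean, wsum


def windowed_correlation(
    x1: np.ndarray, x2: np.ndarray, weights: np.ndarray
) -> float:
    """Weighted Pearson correlation of two signals within one window.

    With unit weights this is the classical sample correlation
    coefficient.  The result is clamped to [-1, 1] against rounding.
    """
    x1 = np.asarray(x1, dtype=np.float64)
    x2 = np.asarray(x2, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValidationError("x1 and x2 must be 1-D vectors of equal length")
    if x1.size < 2:
        raise ValidationError("need at least 2 samples")
    if weights.shape != x1.shape or np.any(weights <= 0):
        raise ValidationError("weights must be positive and match the signals")

    d1, _ = _weighted_moments(x1, weights)
    d2, _ = _weighted_moments(x2, weights)
    v1 = weights @ (d1 * d1)
    v2 = weights @ (d2 * d2)
    scale1 = (1e-12 * max(1.0, float(np.abs(x1).max()))) ** 2
    scale2 = (1e-12 * max(1.0, float(np.abs(x2).max()))) ** 2
    if v1 <= scale1 or v2 <= scale2:
        raise DegenerateWindowError("zero weighted variance within the window")
    r = (weights @ (d1 * d2)) / np.sqrt(v1 * v2)
    return float(np.clip(r, -1.0, 1.0))


@dataclass
class DFNCTensor:
    """Per-subject ``T x F`` matrix of vectorized windowed connectivity.

    Row ``t`` is the strict upper triangle (row-major over pairs i<j) of
    the C x C windowed correlation matrix for the window starting at
    ``window_starts[t]``.  ``feature_index`` maps columns to (i, j) pairs.
    """

    subject_id: str
    data: np.ndarray
    window_starts: np.ndarray
    feature_index: np.ndarray
    fisher_z: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.window_starts = np.asarray(self.window_starts, dtype=np.int64)
        self.feature_index = np.asarray(self.feature_index, dtype=np.int64)
        if self.data.ndim != 2:
            raise ValidationError("tensor data must be 2-D (windows x features)")
        if self.feature_index.shape != (self.data.shape[1], 2):
            raise ValidationError("feature_index must be F x 2")
        if self.window_starts.shape != (self.data.shape[0],):
            raise ValidationError("window_starts must have one entry per window")

    @property
    def n_windows(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def n_components(self) -> int:
        # F = C(C-1)/2  =>  C = (1 + sqrt(1 + 8F)) / 2
        c = int(round((1 + np.sqrt(1 + 8 * self.n_features)) / 2))
        return c

    def to_matrix(self, window: int) -> np.ndarray:
        """Reconstruct the full symmetric C x C matrix for one window
        (unit diagonal)."""
        c = self.n_components
        mat = np.eye(c)
        i, j = self.feature_index.T
        mat[i, j] = self.data[window]
        mat[j, i] = self.data[window]
        return mat


def feature_pairs(n_components: int) -> np.ndarray:
    """Row-major strict upper-triangle (i, j) pairs, i < j."""
    i, j = np.triu_indices(n_components, k=1)
    return np.column_stack([i, j]).astype(np.int64)


def compute_dfnc_tensor(
    tc: ComponentTimeCourses, spec: WindowSpec | None = None, fisher_z: bool = False
) -> DFNCTensor:
    """Estimate the dFNC tensor of one subject.

    For each window position the weighted correlation matrix of all
    component pairs is computed at once (weighted covariance normalized by
    the weighted standard deviations) and its strict upper triangle is
    stored as one tensor row.

    ``fisher_z=True`` applies the Fisher z-transform (arctanh) to the
    correlations; entries are then unbounded rather than in [-1, 1].
    """
    spec = spec or WindowSpec()
    t_total, n_comp = tc.data.shape
    n_win = spec.n_windows(t_total)
    weights = spec.weights
    wsum = weights.sum()
    pairs = feature_pairs(n_comp)
    iu, ju = pairs.T

    starts = np.arange(n_win, dtype=np.int64) * spec.step
    out = np.empty((n_win, pairs.shape[0]))
    for t, s in enumerate(starts):
        x = tc.data[s : s + spec.length]
        centered = x - (weights @ x) / wsum
        cov = (centered * weights[:, None]).T @ centered
        var = np.diag(cov).copy()
        scale = (1e-12 * np.maximum(1.0, np.abs(x).max(axis=0))) ** 2
        bad = np.nonzero(var <= scale)[0]
        if bad.size:
            raise DegenerateWindowError(
                f"subject {tc.subject_id!r}: component {int(bad[0])} is constant "
                f"within the window starting at sample {int(s)}"
            )
        sd = np.sqrt(var)
        corr = cov / np.outer(sd, sd)
        out[t] = np.clip(corr[iu, ju], -1.0, 1.0)

    if fisher_z:
        out = np.arctanh(np.clip(out, -1.0 + 1e-15, 1.0 - 1e-15))
    return DFNCTensor(
        subject_id=tc.subject_id,
        data=out,
        window_starts=starts,
        feature_index=pairs,
        fisher_z=fisher_z,
    )
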