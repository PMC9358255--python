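"""Temporal features of per-subject state vectors.

Two features summarize a subject's state dynamics: the occupancy rate
(fraction of windows spent in each state) and the number of between-state
transitions (adjacent-window label changes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .pipeline import StateVector

__all__ = ["TemporalFeatures", "occupancy_rate", "transition_count", "temporal_features"]


@dataclass
class TemporalFeatures:
    subject_id: str
    ocr: np.ndarray  # length K_opt, fractions summing to 1
    n_transitions: int


def occupancy_rate(sv: StateVector, k_opt: int) -> np.ndarray:
    """Fraction of windows spent in each state; states never visited get 0."""
    labels = sv.labels
    if labels.size == 0:
        raise ValidationError(f"subject {sv.subject_id!r}: empty state vector")
    if labels.min() < 0 or labels.max() >= k_opt:
        raise ValidationError(
            f"subject {sv.subject_id!r}: labels outside [0, {k_opt})"
        )
    return np.bincount(labels, minlength=k_opt) / labels.size


def transition_count(sv: StateVector) -> int:
    """Number of indices t with labels[t] != labels[t-1]."""
    if sv.labels.size == 0:
        raise ValidationError(f"subject {sv.subject_id!r}: empty state vector")
    return int(np.count_nonzero(np.diff(sv.labels)))


def temporal_features(sv: StateVector, k_opt: int) -> TemporalFeatures:
    return TemporalFeatures(
        subject_id=sv.subject_id,
        ocr=occupancy_rate(sv, k_opt),
        n_transitions=transition_count(sv),
    )
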