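"""Uncertainty measures over disease distributions and the invocation threshold.

The framework gates prompting on the uncertainty of the prediction from the
patient's initial description.  Three measures are supported:

``entropy``
    Shannon entropy H(y) = -sum_j y_j ln(y_j) in nats (natural log; the base
    rescales H and the threshold jointly, so gating is base-invariant).
``margin``
    Highest minus second-highest probability; *low* margin means *high*
    uncertainty, so its uncertainty score is the negated margin.
``confidence``
    |max_j y_j - 1/m|, the distance of the top probability from chance;
    negated for the same reason.

The invocation threshold tau is calibrated as the mean uncertainty score of
the diagnosis model's predictions on the *training-fold initial
descriptions* (never complete information, never test data): a prediction
more uncertain than the average training self-description triggers prompts.
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, replace

import numpy as np

from .diagnosis import DiagnosisModel, DiseaseDistribution

__all__ = [
    "UncertaintyConfig",
    "entropy",
    "margin",
    "confidence",
    "uncertainty_score",
    "calibrate_threshold",
    "is_uncertain",
]

_MEASURES = ("entropy", "margin", "confidence")


@dataclass(frozen=True)
class UncertaintyConfig:
    """Chosen uncertainty measure and (optional, calibrated) threshold tau."""

    measure: str = "entropy"
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.measure not in _MEASURES:
            raise ValueError(
                f"unknown uncertainty measure {self.measure!r}; one of {_MEASURES}"
            )
        if self.threshold is not None and self.measure == "entropy" and self.threshold < 0:
            raise ValueError("entropy threshold must be >= 0")


def _probs(dist: DiseaseDistribution | np.ndarray) -> np.ndarray:
    if isinstance(dist, DiseaseDistribution):
        return dist.probabilities
    return np.asarray(dist, dtype=float)


def entropy(dist: DiseaseDistribution | np.ndarray) -> float:
    """Shannon entropy in nats, with 0*ln(0) taken as 0."""
    p = _probs(dist)
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def margin(dist: DiseaseDistribution | np.ndarray) -> float:
    """Highest minus second-highest probability (in [0, 1])."""
    p = _probs(dist)
    if p.size < 2:
        raise ValueError("margin requires at least 2 classes")
    top2 = np.partition(p, -2)[-2:]
    return float(top2[1] - top2[0])


def confidence(dist: DiseaseDistribution | np.ndarray) -> float:
    """Absolute difference between the highest probability and chance (1/m)."""
    p = _probs(dist)
    return float(abs(p.max() - 1.0 / p.size))


def uncertainty_score(dist: DiseaseDistribution | np.ndarray, measure: str = "entropy") -> float:
    """Scalar where larger always means *more* uncertain.

    Entropy is used as-is; margin and confidence are negated because their
    raw values shrink as uncertainty grows.
    """
    if measure == "entropy":
        return entropy(dist)
    if measure == "margin":
        return -margin(dist)
    if measure == "confidence":
        return -confidence(dist)
    raise ValueError(f"unknown uncertainty measure {measure!r}; one of {_MEASURES}")


def calibrate_threshold(
    model: DiagnosisModel,
    training_ids: Sequence[str],
    config: UncertaintyConfig | None = None,
) -> UncertaintyConfig:
    """Set tau to the mean uncertainty of f's predictions on training IDs.

    ``training_ids`` must be the *initial descriptions* of the training fold;
    calibrating on complete information or test data would bias the gate.
    """
    config = config or UncertaintyConfig()
    if len(training_ids) == 0:
        raise ValueError("cannot calibrate a threshold on an empty training set")
    proba = model.predict_proba_batch(list(training_ids))
    scores = [uncertainty_score(row, config.measure) for row in proba]
    return replace(config, threshold=float(np.mean(scores)))


def is_uncertain(dist: DiseaseDistribution | np.ndarray, config: UncertaintyConfig) -> bool:
    """True iff the uncertainty score strictly exceeds the threshold tau."""
    if config.threshold is None:
        raise ValueError("uncertainty threshold is unset; calibrate it first")
    return uncertainty_score(dist, config.measure) > config.threshold
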