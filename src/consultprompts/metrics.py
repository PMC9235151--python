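"""Macro-averaged multiclass evaluation: accuracy, F, AUC, MCC, mean entropy.

Every per-class metric treats the class one-vs-rest.  Macro averages are
unweighted means across the full label set, so rare diseases count as much
as frequent ones.  Conventions for degenerate cases (chosen once, applied
everywhere):

* F and MCC of a class with a zero denominator are 0; classes absent from a
  test fold therefore contribute 0 to the macro average (penalizing).
* AUC of a class with no positives or no negatives in the fold is
  mathematically undefined; such classes are skipped and the macro
  denominator reduced, with a warning.
* AUC ties count 0.5, matching the standard Wilcoxon-Mann-Whitney statistic.
"""

from __future__ import annotations

import math
import warnings
from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np

from .uncertainty import entropy

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "one_vs_rest_counts",
    "accuracy",
    "f_score",
    "macro_f",
    "auc_binary",
    "macro_auc",
    "mcc",
    "macro_mcc",
    "averaged_entropy",
    "evaluate",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def one_vs_rest_counts(
    true_labels: Sequence[str], predicted_labels: Sequence[str], cls: str
) -> ConfusionCounts:
    t = np.asarray(true_labels, dtype=object) == cls
    p = np.asarray(predicted_labels, dtype=object) == cls
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def _check_paired(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> None:
    if len(true_labels) != len(predicted_labels):
        raise ValueError(
            f"{len(true_labels)} true labels vs {len(predicted_labels)} predictions"
        )
    if len(true_labels) == 0:
        raise ValueError("cannot evaluate an empty prediction set")


def accuracy(true_labels: Sequence[str], predicted_labels: Sequence[str]) -> float:
    """Fraction of documents whose top-1 predicted disease is the true one."""
    _check_paired(true_labels, predicted_labels)
    t = np.asarray(true_labels, dtype=object)
    p = np.asarray(predicted_labels, dtype=object)
    return float(np.mean(t == p))


def f_score(counts: ConfusionCounts) -> float:
    """F = 2 TP / (2 TP + FP + FN); 0 when the denominator vanishes."""
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return 0.0
    return 2 * counts.tp / denom


def macro_f(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    label_set: Sequence[str],
) -> float:
    """Unweighted mean of per-class one-vs-rest F over all of ``label_set``."""
    _check_paired(true_labels, predicted_labels)
    return float(
        np.mean([f_score(one_vs_rest_counts(true_labels, predicted_labels, c))
                 for c in label_set])
    )


def auc_binary(positive_scores: Sequence[float], negative_scores: Sequence[float]) -> float:
    """Probability a random positive outscores a random negative; ties = 0.5.

    Computed by explicit pairwise comparison over all |D0| x |D1| pairs — the
    Wilcoxon-Mann-Whitney statistic normalized by the pair count.
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC is undefined without both positive and negative examples")
    gt = (pos[None, :] > neg[:, None]).sum()
    eq = (pos[None, :] == neg[:, None]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


def macro_auc(
    true_labels: Sequence[str],
    score_matrix: np.ndarray,
    label_set: Sequence[str],
) -> float:
    """Unweighted mean of per-class one-vs-rest AUC.

    ``score_matrix[i, j]`` is the predicted probability (or any monotone
    score) of class ``label_set[j]`` for document i.  Classes without both
    positives and negatives in the fold are skipped with a warning and the
    denominator reduced; if no class is scorable, an error is raised.
    """
    t = np.asarray(true_labels, dtype=object)
    scores = np.asarray(score_matrix, dtype=float)
    if scores.shape != (len(t), len(label_set)):
        raise ValueError(
            f"score matrix of shape {scores.shape} does not match "
            f"{len(t)} documents x {len(label_set)} classes"
        )
    aucs = []
    skipped = []
    for j, cls in enumerate(label_set):
        mask = t == cls
        if mask.all() or not mask.any():
            skipped.append(cls)
            continue
        aucs.append(auc_binary(scores[mask, j], scores[~mask, j]))
    if skipped:
        warnings.warn(
            f"macro AUC skipped {len(skipped)} class(es) without both positives "
            f"and negatives: {skipped}", stacklevel=2,
        )
    if not aucs:
        raise ValueError("no class had both positive and negative examples")
    return float(np.mean(aucs))


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor vanishes."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / denom


def macro_mcc(
    true_labels: Sequence[str],
    predicted_labels: Sequence[str],
    label_set: Sequence[str],
) -> float:
    """Unweighted mean of per-class one-vs-rest MCC over all of ``label_set``."""
    _check_paired(true_labels, predicted_labels)
    return float(
        np.mean([mcc(one_vs_rest_counts(true_labels, predicted_labels, c))
                 for c in label_set])
    )


def averaged_entropy(distributions: Sequence) -> float:
    """Mean Shannon entropy (nats) across test-document predictions."""
    if len(distributions) == 0:
        raise ValueError("cannot average entropy over an empty collection")
    return float(np.mean([entropy(d) for d in distributions]))


@dataclass(frozen=True)
class EvaluationReport:
    """All evaluation metrics for one set of predictions."""

    accuracy: float
    macro_f: float
    macro_auc: float
    macro_mcc: float
    averaged_entropy: float
    n_evaluated: int
    per_class: dict[str, dict[str, float]] = field(default_factory=dict)

    def scalars(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "macro_f": self.macro_f,
            "macro_auc": self.macro_auc,
            "macro_mcc": self.macro_mcc,
            "averaged_entropy": self.averaged_entropy,
        }


def evaluate(
    true_labels: Sequence[str],
    score_matrix: np.ndarray,
    label_set: Sequence[str],
) -> EvaluationReport:
    """Full evaluation from true labels and a predicted-probability matrix.

    The predicted label of each document is the argmax column of its row
    (ties to the first label in ``label_set`` order).
    """
    _check_paired(true_labels, np.asarray(score_matrix)[:, 0])
    scores = np.asarray(score_matrix, dtype=float)
    labels = list(label_set)
    predicted = [labels[j] for j in np.argmax(scores, axis=1)]
    per_class: dict[str, dict[str, float]] = {}
    for j, cls in enumerate(labels):
        counts = one_vs_rest_counts(true_labels, predicted, cls)
        row = {"f": f_score(counts), "mcc": mcc(counts)}
        mask = np.asarray(true_labels, dtype=object) == cls
        if mask.any() and not mask.all():
            row["auc"] = auc_binary(scores[mask, j], scores[~mask, j])
        else:
            row["auc"] = float("nan")
        per_class[cls] = row
    return EvaluationReport(
        accuracy=accuracy(true_labels, predicted),
        macro_f=macro_f(true_labels, predicted, labels),
        macro_auc=macro_auc(true_labels, scores, labels),
        macro_mcc=macro_mcc(true_labels, predicted, labels),
        averaged_entropy=averaged_entropy(list(scores)),
        n_evaluated=len(true_labels),
        per_class=per_class,
    )
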