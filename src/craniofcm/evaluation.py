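"""Cluster-to-label alignment, binary sexing metrics, stability protocol.

An unsupervised partition has anonymous cluster indices; scoring it
against sex labels first requires the cluster→label bijection that
maximizes overall accuracy (found by exhaustive permutation enumeration,
exact for small cluster counts).  TPR is the recall of the positive
(male) class, TNR the recall of the other (female) class, ACC the overall
proportion correct; all are reported as percentages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations
from typing import Callable, Sequence

import numpy as np

from .datamodel import FeatureMatrix, FitResult, ValidationError

logger = logging.getLogger(__name__)

MAX_EXHAUSTIVE_CLUSTERS = 8


@dataclass
class EvalReport:
    """Alignment-based classification report for a binary partition."""

    accuracy: float  # percent
    tpr: float  # percent, recall of the positive (male) class
    tnr: float  # percent, recall of the negative (female) class
    mapping: dict
    confusion: np.ndarray  # rows = truth (neg, pos), cols = predicted

    def to_dict(self) -> dict:
        return {
            "acc": self.accuracy,
            "tpr": self.tpr,
            "tnr": self.tnr,
            "mapping": {str(k): str(v) for k, v in self.mapping.items()},
            "confusion": self.confusion.tolist(),
        }


@dataclass
class StabilitySummary:
    """Per-seed accuracies of repeated randomly-initialized fits."""

    accuracies: list[float]
    errors: list[str | None]
    minimum: float
    maximum: float
    mean: float


def align_clusters(
    pred: Sequence[int], truth: Sequence
) -> dict:
    """Best cluster→label bijection by exhaustive permutation search.

    Maximizes overall accuracy; ties break toward the lexicographically
    smallest mapping (clusters in index order, labels in sorted order).
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValidationError(
            f"pred has length {pred.size}, truth has length {truth.size}"
        )
    clusters = sorted(set(pred.tolist()))
    labels = sorted(set(np.asarray(truth).tolist()))
    if len(clusters) > MAX_EXHAUSTIVE_CLUSTERS:
        raise ValidationError(
            f"exhaustive alignment supports at most {MAX_EXHAUSTIVE_CLUSTERS} clusters"
        )
    if len(clusters) > len(labels):
        raise ValidationError(
            f"{len(clusters)} clusters cannot be injectively mapped onto "
            f"{len(labels)} labels"
        )
    best_mapping = None
    best_correct = -1
    # permutations() yields in lexicographic order of the sorted label list,
    # so the first argmax encountered is the lexicographically smallest
    for perm in permutations(labels, len(clusters)):
        mapping = dict(zip(clusters, perm))
        correct = int(np.sum([mapping[p] == t for p, t in zip(pred, truth)]))
        if correct > best_correct:
            best_correct = correct
            best_mapping = mapping
    return best_mapping


def apply_mapping(pred: Sequence[int], mapping: dict) -> np.ndarray:
    return np.asarray([mapping[p] for p in np.asarray(pred)])


def score(pred_aligned: Sequence, truth: Sequence, positive_label) -> EvalReport:
    """Binary classification rates from aligned labels, as percentages."""
    pred_aligned = np.asarray(pred_aligned)
    truth = np.asarray(truth)
    if pred_aligned.shape != truth.shape:
        raise ValidationError("prediction and truth lengths differ")
    labels = sorted(set(truth.tolist()))
    if len(labels) > 2:
        raise ValidationError(f"binary metrics need <= 2 labels, got {labels}")
    if positive_label not in labels:
        raise ValidationError(f"positive label {positive_label!r} absent from truth")
    negative = [l for l in labels if l != positive_label]
    negative_label = negative[0] if negative else None

    pos = truth == positive_label
    neg = ~pos
    correct = pred_aligned == truth
    tpr = 100.0 * correct[pos].mean() if pos.any() else float("nan")
    tnr = 100.0 * correct[neg].mean() if neg.any() else float("nan")
    acc = 100.0 * correct.mean()
    order = [negative_label, positive_label]
    confusion = np.array(
        [
            [int(np.sum((truth == t) & (pred_aligned == p))) for p in order]
            for t in order
        ]
    )
    mapping = {}  # identity on labels; kept for report symmetry
    for l in labels:
        mapping[l] = l
    return EvalReport(acc, tpr, tnr, mapping, confusion)


def aligned_accuracy(hard_labels: Sequence[int], truth: Sequence) -> float:
    """Overall percent correct under the best cluster→label mapping.

    Works for any label count the exhaustive alignment supports, unlike
    the binary :func:`score` report.
    """
    mapping = align_clusters(hard_labels, truth)
    aligned = apply_mapping(hard_labels, mapping)
    return 100.0 * float(np.mean(aligned == np.asarray(truth)))


def evaluate_partition(
    hard_labels: Sequence[int], truth: Sequence, positive_label="M"
) -> EvalReport:
    """Align anonymous clusters to labels, then score (binary truth)."""
    mapping = align_clusters(hard_labels, truth)
    report = score(apply_mapping(hard_labels, mapping), truth, positive_label)
    report.mapping = mapping
    return report


def stability_run(
    fit: Callable[[FeatureMatrix, int], FitResult],
    X: FeatureMatrix,
    truth: Sequence,
    n_reps: int,
    seed: int,
    positive_label="M",
) -> StabilitySummary:
    """Repeat a randomly-initialized fit and summarize accuracy spread.

    ``fit(X, seed)`` must return a :class:`FitResult`; run r uses seed
    ``seed + r`` so the whole protocol is deterministic given the master
    seed.  A failing run records its error message and is excluded from
    the min/max/mean summary rather than aborting the protocol.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    accuracies: list[float] = []
    errors: list[str | None] = []
    for r in range(n_reps):
        try:
            result = fit(X, seed + r)
            accuracies.append(aligned_accuracy(result.hard_labels, truth))
            errors.append(None)
        except Exception as exc:  # recorded, not fatal
            logger.warning("stability run %d failed: %s", r, exc)
            accuracies.append(float("nan"))
            errors.append(str(exc))
    ok = [a for a in accuracies if not np.isnan(a)]
    if not ok:
        raise ValidationError("every stability run failed")
    return StabilitySummary(
        accuracies=accuracies,
        errors=errors,
        minimum=float(min(ok)),
        maximum=float(max(ok)),
        mean=float(np.mean(ok)),
    )
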