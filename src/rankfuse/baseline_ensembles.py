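"""Classical decision-fusion baselines sharing the EnsembleScoreSet contract.

Five rules commonly used to combine M classifiers' per-class confidence
scores: maximum probability, average probability, sum rule, majority
voting, and an accuracy-weighted average. Average probability and the sum
rule always agree on labels (sum = M * mean); both are kept because their
per-class fused scores differ in scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fusion_core import EnsembleScoreSet

__all__ = [
    "BASELINE_METHODS",
    "BaselineResult",
    "baseline_fuse",
    "accuracy_weights",
]

BASELINE_METHODS = (
    "maximum_probability",
    "average_probability",
    "sum_rule",
    "majority_voting",
    "weighted_average",
)

_ALIASES = {
    "max": "maximum_probability",
    "avg": "average_probability",
    "sum": "sum_rule",
    "vote": "majority_voting",
    "weighted": "weighted_average",
}


def resolve_method(name: str) -> str:
    name = name.strip().lower()
    name = _ALIASES.get(name, name)
    if name not in BASELINE_METHODS:
        raise ValueError(
            f"unknown baseline method {name!r}; choose from {BASELINE_METHODS}"
        )
    return name


@dataclass
class BaselineResult:
    method: str
    labels: np.ndarray        # fused label per sample
    indices: np.ndarray       # fused class index per sample
    class_scores: np.ndarray  # per-class fused score (higher = better)


def accuracy_weights(accuracies) -> np.ndarray:
    """Per-classifier weights proportional to validation accuracy.

    weights = accuracies / sum(accuracies); all-zero accuracies are an
    error, negative accuracies are rejected.
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.ndim != 1 or acc.size == 0:
        raise ValueError("accuracies must be a non-empty 1-D sequence")
    if np.any(acc < 0):
        raise ValueError("accuracies must be nonnegative")
    total = acc.sum()
    if total == 0:
        raise ValueError("cannot derive weights from all-zero accuracies")
    return acc / total


def _majority_vote(scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Plurality of per-classifier argmax labels; ties broken by highest
    mean confidence among the tied classes, then by class order."""
    m, n, c = scores.shape
    per_model_argmax = scores.argmax(axis=-1)               # (M, n)
    votes = np.zeros((n, c), dtype=float)
    for i in range(m):
        votes[np.arange(n), per_model_argmax[i]] += 1.0
    mean_conf = scores.mean(axis=0)                         # (n, C)
    # lexsort ascending by (votes, mean_conf, descending class index):
    # the last position then holds the winner with first-class tie-break
    class_desc = np.broadcast_to(-np.arange(c), (n, c))
    order = np.lexsort((class_desc, mean_conf, votes), axis=-1)
    winner = order[:, -1]
    return winner, votes


def baseline_fuse(
    scores: EnsembleScoreSet,
    method: str,
    weights=None,
) -> BaselineResult:
    """Fuse a validated score set with one of the classical rules.

    Parameters
    ----------
    scores : EnsembleScoreSet
        Validated, aligned confidence matrices.
    method : str
        One of ``maximum_probability``, ``average_probability``,
        ``sum_rule``, ``majority_voting``, ``weighted_average`` (short
        aliases max/avg/sum/vote/weighted accepted).
    weights : sequence of float, optional
        Required for ``weighted_average``: M nonnegative reals,
        renormalized to sum 1 (see :func:`accuracy_weights`).
    """
    method = resolve_method(method)
    arr = scores.scores
    if method == "maximum_probability":
        fused = arr.max(axis=0)
    elif method == "average_probability":
        fused = arr.mean(axis=0)
    elif method == "sum_rule":
        fused = arr.sum(axis=0)
    elif method == "weighted_average":
        if weights is None:
            raise ValueError("weighted_average requires per-classifier weights")
        w = np.asarray(weights, dtype=float)
        if w.shape != (scores.n_models,):
            raise ValueError(
                f"weights must have length M={scores.n_models}, got {w.shape}"
            )
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            w = accuracy_weights(w)
        fused = np.tensordot(w, arr, axes=(0, 0))
    else:  # majority_voting
        idx, votes = _majority_vote(arr)
        labels = np.asarray(scores.class_labels, dtype=object)[idx]
        return BaselineResult(method=method, labels=labels, indices=idx, class_scores=votes)

    idx = fused.argmax(axis=-1)
    labels = np.asarray(scores.class_labels, dtype=object)[idx]
    return BaselineResult(method=method, labels=labels, indices=idx, class_scores=fused)
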