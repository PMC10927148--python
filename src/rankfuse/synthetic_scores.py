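"""Seeded simulator of classifier score banks.

Emulates what M softmax classifiers (e.g. three fine-tuned CNNs on an
imbalanced 2-3-class CT task) would emit: per-sample, per-class
confidence vectors that sum to 1, with controllable per-model accuracy,
confidence sharpness, class imbalance and error correlation. The defaults
mirror a 3-class task with class supports 120/561/416 and base-model
accuracies around 0.97-0.995.

Score model: each sample/model pair draws a Dirichlet-style vector —
independent Gamma(1) variates with the shape of one "target" class
boosted by ``concentration``, normalized to sum 1 — so the target class
almost always carries the argmax. The target is the true class with
probability equal to the model's accuracy, otherwise a wrong class; with
probability ``error_correlation`` all erring models on a sample share one
common wrong target (correlated failure), otherwise each errs on its own
uniformly drawn wrong class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .baseline_ensembles import BASELINE_METHODS, accuracy_weights, baseline_fuse
from .fusion_core import EnsembleScoreSet, fuse

__all__ = ["SyntheticConfig", "simulate_bank", "condorcet_check"]

_DEFAULT_PROPORTIONS = (120 / 1097, 561 / 1097, 416 / 1097)
_DEFAULT_ACCURACIES = (0.9902, 0.9726, 0.9945)


@dataclass
class SyntheticConfig:
    """Generative settings for one synthetic score bank.

    Attributes
    ----------
    n_samples : number of samples.
    class_proportions : C nonnegative reals summing to 1 (default: an
        imbalanced 3-class split 120/561/416 normalized).
    model_accuracies : per-model probability of drawing the true class as
        the confidence target; each must exceed chance 1/C.
    concentration : positive Gamma shape boost on the target class;
        larger values give sharper (more one-hot) confidence vectors.
    error_correlation : probability in [0, 1] that a sample's erring
        models share a single common wrong target.
    seed : integer seed; the bank is fully reproducible from it.
    class_labels / classifier_names : optional name overrides.
    """

    n_samples: int = 1097
    class_proportions: Sequence[float] = _DEFAULT_PROPORTIONS
    model_accuracies: Sequence[float] = _DEFAULT_ACCURACIES
    concentration: float = 10.0
    error_correlation: float = 0.0
    seed: int = 0
    class_labels: Sequence[str] | None = None
    classifier_names: Sequence[str] | None = None

    def __post_init__(self):
        self.class_proportions = tuple(float(p) for p in self.class_proportions)
        self.model_accuracies = tuple(float(a) for a in self.model_accuracies)
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        c = len(self.class_proportions)
        if c < 2:
            raise ValueError("need at least two classes")
        if any(p < 0 for p in self.class_proportions):
            raise ValueError("class proportions must be nonnegative")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1 (within 1e-9)")
        if not self.model_accuracies:
            raise ValueError("need at least one model accuracy")
        for a in self.model_accuracies:
            if not (1.0 / c < a <= 1.0):
                raise ValueError(
                    f"model accuracy {a} must lie in (1/C, 1] = ({1.0 / c:.4g}, 1]"
                )
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if not 0.0 <= self.error_correlation <= 1.0:
            raise ValueError("error_correlation must be in [0, 1]")
        if self.class_labels is None:
            self.class_labels = tuple(f"class_{j + 1}" for j in range(c))
        else:
            self.class_labels = tuple(str(s) for s in self.class_labels)
            if len(self.class_labels) != c:
                raise ValueError("class_labels length must match proportions")
        if self.classifier_names is None:
            self.classifier_names = tuple(
                f"model_{i + 1}" for i in range(len(self.model_accuracies))
            )
        else:
            self.classifier_names = tuple(str(s) for s in self.classifier_names)
            if len(self.classifier_names) != len(self.model_accuracies):
                raise ValueError("classifier_names length must match accuracies")

    @property
    def n_classes(self) -> int:
        return len(self.class_proportions)

    @property
    def n_models(self) -> int:
        return len(self.model_accuracies)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "class_proportions": list(self.class_proportions),
            "model_accuracies": list(self.model_accuracies),
            "concentration": self.concentration,
            "error_correlation": self.error_correlation,
            "seed": self.seed,
            "class_labels": list(self.class_labels),
            "classifier_names": list(self.classifier_names),
        }


def simulate_bank(cfg: SyntheticConfig) -> tuple[EnsembleScoreSet, np.ndarray]:
    """Draw one score bank and its ground-truth labels.

    Returns the (M, n, C) score set and an object array of true class
    labels. Rows sum to 1 up to floating point; strict validation passes.
    """
    rng = np.random.default_rng(cfg.seed)
    n, c, m = cfg.n_samples, cfg.n_classes, cfg.n_models
    truth_idx = rng.choice(c, size=n, p=np.asarray(cfg.class_proportions))
    # one candidate shared wrong class per sample, plus the per-sample coin
    # deciding whether erring models use it
    shared_offset = rng.integers(1, c, size=n)
    shared_wrong = (truth_idx + shared_offset) % c
    shared_event = rng.random(n) < cfg.error_correlation

    scores = np.empty((m, n, c), dtype=float)
    for i, acc in enumerate(cfg.model_accuracies):
        correct = rng.random(n) < acc
        own_offset = rng.integers(1, c, size=n)
        own_wrong = (truth_idx + own_offset) % c
        target = np.where(correct, truth_idx, np.where(shared_event, shared_wrong, own_wrong))
        alpha = np.ones((n, c))
        alpha[np.arange(n), target] += cfg.concentration
        gam = rng.gamma(shape=alpha)
        scores[i] = gam / gam.sum(axis=1, keepdims=True)

    sset = EnsembleScoreSet(
        scores=scores,
        sample_ids=[f"s{j:06d}" for j in range(n)],
        class_labels=list(cfg.class_labels),
        classifier_names=list(cfg.classifier_names),
    )
    truth = np.asarray(cfg.class_labels, dtype=object)[truth_idx]
    return sset, truth


def condorcet_check(cfg: SyntheticConfig, k: int = 2) -> dict:
    """Fused vs base accuracies under independent, equally accurate models.

    Simulates a bank, runs the fuzzy-rank fusion (top-k cut ``k``) and all
    baseline rules, and counts the samples the fusion gets right while
    exactly one or exactly two base models err — the regime where
    independent errors let an ensemble beat its members.
    """
    if cfg.error_correlation != 0.0:
        raise ValueError("condorcet_check requires error_correlation = 0")
    if len(set(cfg.model_accuracies)) != 1:
        raise ValueError("condorcet_check requires equal model accuracies")
    sset, truth = simulate_bank(cfg)
    base_correct = np.stack(
        [sset.scores[i].argmax(axis=1) for i in range(cfg.n_models)]
    ) == np.array([list(cfg.class_labels).index(t) for t in truth])
    base_acc = {
        name: float(base_correct[i].mean())
        for i, name in enumerate(cfg.classifier_names)
    }
    result = fuse(sset, k=k)
    fused_correct = result.fused_label == truth
    n_wrong = (~base_correct).sum(axis=0)
    methods = {"fuzzy_rank": float(fused_correct.mean())}
    weights = accuracy_weights(list(cfg.model_accuracies))
    for method in BASELINE_METHODS:
        w = weights if method == "weighted_average" else None
        res = baseline_fuse(sset, method, weights=w)
        methods[method] = float((res.labels == truth).mean())
    return {
        "n_samples": cfg.n_samples,
        "base_accuracy": base_acc,
        "method_accuracy": methods,
        "fused_correct_one_model_wrong": int(np.sum(fused_correct & (n_wrong == 1))),
        "fused_correct_two_models_wrong": int(np.sum(fused_correct & (n_wrong == 2))),
    }
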