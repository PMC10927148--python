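"""Fuzzy-rank decision fusion.

Given M classifiers' per-class confidence scores for each sample, the
fusion rule is:

1. normalize each classifier's row of confidences to sum to 1;
2. transform every confidence into a fuzzy rank with the Mitscherlich map
   (lower rank value = better);
3. per classifier and sample, keep only the k best-ranked classes
   (the "top-k" set);
4. fuzzy rank sum  FRS_c = sum over classifiers of the fuzzy rank if class
   c is in that classifier's top-k, else the penalty P_R = 1;
5. complemented confidence sum  CCFS_c = 1 - mean over classifiers of the
   confidence if c is in the top-k, else the penalty P_CoF = 0
   (the "literal" variant omits the final complement);
6. final decision score  FDS_c = FRS_c * CCFS_c, and the fused label is
   the class minimizing FDS (ties broken by class order).

The penalties make a class that no classifier ranks highly attain
FDS = M exactly, so it can never beat a genuinely supported class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .rank_functions import MITSCHERLICH, RankFunction, rank_transform

__all__ = [
    "EnsembleScoreSet",
    "TopKSelection",
    "FusionResult",
    "PENALTY_RANK",
    "PENALTY_CONFIDENCE",
    "validate_scores",
    "ordinal_ranks",
    "select_topk",
    "fuzzy_rank_sum",
    "complement_confidence_sum",
    "final_decision_score",
    "decide",
    "fuse",
]

logger = logging.getLogger(__name__)

#: rank penalty for a class outside a classifier's top-k; equals the
#: Mitscherlich transform at confidence 0.
PENALTY_RANK = 1.0
#: confidence penalty for a class outside a classifier's top-k.
PENALTY_CONFIDENCE = 0.0

ROW_SUM_TOLERANCE = 1e-6


@dataclass
class EnsembleScoreSet:
    """M aligned confidence matrices plus sample/class/classifier labels.

    ``scores`` has shape (M, n_samples, n_classes); ``scores[i, s, c]`` is
    classifier i's confidence that sample s belongs to class c.
    """

    scores: np.ndarray
    sample_ids: list
    class_labels: list
    classifier_names: list = field(default=None)

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 3:
            raise ValueError("scores must have shape (M, n_samples, n_classes)")
        m, n, c = self.scores.shape
        if m < 1:
            raise ValueError("need at least one classifier (M >= 1)")
        if c < 2:
            raise ValueError("need at least two classes (C >= 2)")
        self.sample_ids = list(self.sample_ids)
        self.class_labels = list(self.class_labels)
        if self.classifier_names is None:
            self.classifier_names = [f"model_{i + 1}" for i in range(m)]
        self.classifier_names = list(self.classifier_names)
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match score matrices")
        if len(self.class_labels) != c:
            raise ValueError("class_labels length does not match score matrices")
        if len(self.classifier_names) != m:
            raise ValueError("classifier_names length does not match M")

    @property
    def n_models(self) -> int:
        return self.scores.shape[0]

    @property
    def n_samples(self) -> int:
        return self.scores.shape[1]

    @property
    def n_classes(self) -> int:
        return self.scores.shape[2]

    @property
    def matrices(self) -> list[np.ndarray]:
        """The M confidence matrices as a list of (n_samples, C) arrays."""
        return [self.scores[i] for i in range(self.n_models)]

    @classmethod
    def from_dataframes(
        cls,
        frames: Sequence[pd.DataFrame],
        classifier_names: Sequence[str] | None = None,
    ) -> "EnsembleScoreSet":
        """Build from M DataFrames indexed by sample id with class columns.

        All frames must share identical index (sample order) and columns
        (class order); class identity is by column label.
        """
        if not frames:
            raise ValueError("need at least one score frame")
        first = frames[0]
        for j, f in enumerate(frames[1:], start=2):
            if list(f.columns) != list(first.columns):
                raise ValueError(
                    f"class labels of frame {j} {list(f.columns)} do not match "
                    f"frame 1 {list(first.columns)}"
                )
            if list(f.index) != list(first.index):
                raise ValueError(f"sample ids of frame {j} do not match frame 1")
        scores = np.stack([f.to_numpy(dtype=float) for f in frames])
        return cls(
            scores=scores,
            sample_ids=list(first.index),
            class_labels=list(first.columns),
            classifier_names=list(classifier_names) if classifier_names else None,
        )

    def to_dataframes(self) -> list[pd.DataFrame]:
        return [
            pd.DataFrame(
                self.scores[i],
                index=pd.Index(self.sample_ids, name="sample_id"),
                columns=self.class_labels,
            )
            for i in range(self.n_models)
        ]


@dataclass(frozen=True)
class TopKSelection:
    """Boolean top-k membership, shape (M, n_samples, n_classes)."""

    k: int
    membership: np.ndarray

    def __post_init__(self):
        counts = self.membership.sum(axis=-1)
        if not np.all(counts == self.k):
            raise ValueError("each per-classifier, per-sample top-k set must have exactly k classes")


@dataclass
class FusionResult:
    """Per-sample, per-class fusion scores and the fused decision.

    ``frs`` (fuzzy rank sum, in [0, M]), ``ccfs`` (complemented confidence
    sum, in [0, 1] for the complement variant) and ``fds = frs * ccfs`` are
    (n_samples, n_classes) arrays; ``fused_label`` holds the argmin-FDS
    class per sample.
    """

    frs: np.ndarray
    ccfs: np.ndarray
    fds: np.ndarray
    fused_label: np.ndarray
    fused_index: np.ndarray
    sample_ids: list
    class_labels: list
    k: int
    variant: str
    penalties: tuple = (PENALTY_RANK, PENALTY_CONFIDENCE)

    def to_frame(self) -> pd.DataFrame:
        """Predictions table: sample_id, fused_label, fds_<class>..."""
        data = {"sample_id": self.sample_ids, "fused_label": self.fused_label}
        for j, cls_ in enumerate(self.class_labels):
            data[f"fds_{cls_}"] = self.fds[:, j]
        return pd.DataFrame(data)

    def class_scores(self) -> np.ndarray:
        """Monotone 'higher is better' scores derived from FDS for ROC
        analysis: s_c = (M_eff - FDS_c) normalized to sum 1 per sample,
        where M_eff = max attainable FDS."""
        m_eff = float(self.fds.max()) if self.fds.size else 1.0
        m_eff = max(m_eff, 1e-12)
        raw = m_eff - self.fds
        denom = raw.sum(axis=1, keepdims=True)
        denom[denom == 0] = 1.0
        return raw / denom


def validate_scores(
    raw: EnsembleScoreSet,
    tolerance: float = ROW_SUM_TOLERANCE,
    policy: str = "renormalize",
) -> EnsembleScoreSet:
    """Check (and under ``policy='renormalize'`` enforce) row-stochasticity.

    Every classifier's confidence row must sum to 1: under ``'strict'`` a
    deviation beyond ``tolerance`` is an error; under ``'renormalize'``
    rows with positive sum are divided by their sum (with a logged
    warning when any row actually deviated). Negative entries and
    zero-sum rows are always errors.
    """
    if policy not in ("strict", "renormalize"):
        raise ValueError(f"unknown normalization policy {policy!r}")
    scores = raw.scores
    if np.any(scores < 0):
        i, s, c = np.argwhere(scores < 0)[0]
        raise ValueError(
            f"negative confidence {scores[i, s, c]!r} for classifier "
            f"{raw.classifier_names[i]!r}, sample {raw.sample_ids[s]!r}, "
            f"class {raw.class_labels[c]!r}"
        )
    sums = scores.sum(axis=-1)
    if np.any(sums <= 0):
        i, s = np.argwhere(sums <= 0)[0]
        raise ValueError(
            f"zero-sum confidence row for classifier "
            f"{raw.classifier_names[i]!r}, sample {raw.sample_ids[s]!r}"
        )
    deviating = np.abs(sums - 1.0) > tolerance
    if policy == "strict":
        if np.any(deviating):
            i, s = np.argwhere(deviating)[0]
            raise ValueError(
                f"confidence row sums to {sums[i, s]!r} (tolerance {tolerance}) "
                f"for classifier {raw.classifier_names[i]!r}, sample "
                f"{raw.sample_ids[s]!r}; use policy='renormalize' to rescale"
            )
        normalized = scores
    else:
        if np.any(deviating):
            logger.warning(
                "renormalized %d confidence rows whose sums deviated from 1 "
                "by more than %g",
                int(deviating.sum()),
                tolerance,
            )
        normalized = scores / sums[..., None]
    return EnsembleScoreSet(
        scores=normalized,
        sample_ids=raw.sample_ids,
        class_labels=raw.class_labels,
        classifier_names=raw.classifier_names,
    )


def ordinal_ranks(ranks: np.ndarray) -> np.ndarray:
    """Ordinal rank (1 = best) of each class by ascending fuzzy-rank value.

    Ties are broken by class position (stable sort), so equal rank values
    give the earlier-listed class the better ordinal.
    """
    ranks = np.asarray(ranks, dtype=float)
    c = ranks.shape[-1]
    order = np.argsort(ranks, axis=-1, kind="stable")
    ordinals = np.empty(ranks.shape, dtype=np.int64)
    positions = np.broadcast_to(np.arange(1, c + 1), ranks.shape)
    np.put_along_axis(ordinals, order, positions, axis=-1)
    return ordinals


def select_topk(ordinals: np.ndarray, k: int) -> TopKSelection:
    """Top-k membership: classes whose ordinal rank is <= k."""
    ordinals = np.asarray(ordinals)
    c = ordinals.shape[-1]
    if not 1 <= k <= c:
        raise ValueError(f"k must be in 1..{c}, got {k}")
    return TopKSelection(k=k, membership=ordinals <= k)


def fuzzy_rank_sum(ranks: np.ndarray, sel: TopKSelection) -> np.ndarray:
    """FRS: sum of fuzzy ranks over classifiers, penalty P_R = 1 outside
    the top-k. ``ranks`` has shape (M, n_samples, C); returns (n_samples, C)."""
    ranks = np.asarray(ranks, dtype=float)
    return np.where(sel.membership, ranks, PENALTY_RANK).sum(axis=0)


def complement_confidence_sum(
    scores: EnsembleScoreSet | np.ndarray,
    sel: TopKSelection,
    variant: str = "complement",
) -> np.ndarray:
    """CCFS: (one minus) the mean included confidence over classifiers.

    ``variant='complement'`` (default) returns 1 - mean(included CoF),
    penalizing classes with little confidence mass; ``'literal'`` returns
    the plain mean (kept for auditability — under the argmin decision it
    rewards unsupported classes and is not recommended).
    """
    if variant not in ("complement", "literal"):
        raise ValueError(f"unknown CCFS variant {variant!r}")
    arr = scores.scores if isinstance(scores, EnsembleScoreSet) else np.asarray(scores, dtype=float)
    m = arr.shape[0]
    included = np.where(sel.membership, arr, PENALTY_CONFIDENCE).sum(axis=0) / m
    if variant == "literal":
        return included
    return 1.0 - included


def final_decision_score(frs: np.ndarray, ccfs: np.ndarray) -> np.ndarray:
    """FDS = FRS * CCFS, elementwise."""
    frs = np.asarray(frs, dtype=float)
    ccfs = np.asarray(ccfs, dtype=float)
    if frs.shape != ccfs.shape:
        raise ValueError("FRS and CCFS shapes differ")
    return frs * ccfs


def decide(fds: np.ndarray, class_labels: Sequence | None = None):
    """Fused label per sample: argmin of FDS over classes, ties broken by
    class order. Returns (indices, labels-or-None)."""
    fds = np.asarray(fds, dtype=float)
    idx = np.argmin(fds, axis=-1)
    if class_labels is None:
        return idx, None
    labels = np.asarray(list(class_labels), dtype=object)[idx]
    return idx, labels


def fuse(
    scores: EnsembleScoreSet,
    k: int = 2,
    variant: str = "complement",
    rank_function: RankFunction = MITSCHERLICH,
    policy: str = "renormalize",
    tolerance: float = ROW_SUM_TOLERANCE,
) -> FusionResult:
    """Run the full fuzzy-rank fusion pipeline on a score set.

    Composes validation, the rank transform, top-k selection, FRS/CCFS/FDS
    and the argmin decision. Deterministic: identical inputs give
    identical outputs.
    """
    k = int(k)
    if not 1 <= k <= scores.n_classes:
        raise ValueError(f"k must be in 1..{scores.n_classes}, got {k}")
    validated = validate_scores(scores, tolerance=tolerance, policy=policy)
    ranks = np.stack(
        [rank_transform(m, rank_function) for m in validated.matrices]
    )
    ordinals = ordinal_ranks(ranks)
    sel = select_topk(ordinals, k)
    frs = fuzzy_rank_sum(ranks, sel)
    ccfs = complement_confidence_sum(validated, sel, variant=variant)
    fds = final_decision_score(frs, ccfs)
    idx, labels = decide(fds, validated.class_labels)
    return FusionResult(
        frs=frs,
        ccfs=ccfs,
        fds=fds,
        fused_label=labels,
        fused_index=idx,
        sample_ids=validated.sample_ids,
        class_labels=validated.class_labels,
        k=k,
        variant=variant,
    )
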