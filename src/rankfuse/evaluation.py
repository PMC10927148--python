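"""Multiclass evaluation: confusion-matrix metrics, macro aggregation,
one-vs-rest ROC-AUC, and McNemar's paired test.

Per-class precision, recall and F1 are computed one-vs-rest from the
confusion matrix (TP on the diagonal, FP = column sum - TP,
FN = row sum - TP; zero denominators yield 0 with a warning). Headline
aggregates are macro (unweighted) means; support-weighted means are
reported additionally. Display rounding is 4 decimals, half away from
zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import sklearn.metrics as skm
from scipy import stats

__all__ = [
    "EvaluationReport",
    "McNemarResult",
    "confusion_matrix",
    "classification_report",
    "macro_average",
    "weighted_average",
    "round_display",
    "roc_auc_ovr",
    "mcnemar_test",
    "evaluate_predictions",
]

#: discordant-pair threshold below which McNemar's test uses the exact
#: binomial p-value rather than the continuity-corrected chi-square.
MCNEMAR_EXACT_THRESHOLD = 25


def round_display(x: float, ndigits: int = 4) -> float:
    """Round half away from zero (0.92945 -> 0.9295), for display."""
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def confusion_matrix(truth, pred, class_labels) -> pd.DataFrame:
    """C x C count table; rows = true class, columns = predicted class."""
    truth = np.asarray(list(truth), dtype=object)
    pred = np.asarray(list(pred), dtype=object)
    if truth.shape != pred.shape:
        raise ValueError(
            f"truth ({truth.size}) and predictions ({pred.size}) differ in length"
        )
    labels = list(class_labels)
    known = set(labels)
    for name, vec in (("truth", truth), ("prediction", pred)):
        unknown = sorted({str(v) for v in vec if v not in known})
        if unknown:
            raise ValueError(f"unknown {name} label(s): {unknown}")
    if truth.size == 0:
        counts = np.zeros((len(labels), len(labels)), dtype=int)
    else:
        counts = skm.confusion_matrix(truth, pred, labels=labels)
    return pd.DataFrame(counts, index=pd.Index(labels, name="true"),
                        columns=pd.Index(labels, name="predicted"))


def macro_average(values) -> float:
    """Unweighted arithmetic mean of per-class metric values."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("macro average of an empty sequence")
    return float(arr.mean())


def weighted_average(values, supports) -> float:
    """Support-weighted mean of per-class metric values."""
    v = np.asarray(list(values), dtype=float)
    w = np.asarray(list(supports), dtype=float)
    if v.shape != w.shape or v.size == 0:
        raise ValueError("values and supports must be non-empty and aligned")
    return float((v * w).sum() / w.sum())


@dataclass
class EvaluationReport:
    """Confusion matrix, per-class and aggregate metrics.

    ``per_class`` is indexed by class with columns precision, recall, f1,
    support; macro aggregates are unweighted means, ``accuracy`` is
    trace/total (equal to the support-weighted mean of per-class recalls).
    """

    confusion: pd.DataFrame
    per_class: pd.DataFrame
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    rounding: int = 4

    @property
    def class_labels(self) -> list:
        return list(self.per_class.index)

    def to_dict(self, percent: bool = False) -> dict:
        scale = 100.0 if percent else 1.0
        nd = self.rounding - 2 if percent else self.rounding
        r = lambda x: round_display(x * scale, nd)
        return {
            "scale": "percent" if percent else "fraction",
            "accuracy": r(self.accuracy),
            "macro_precision": r(self.macro_precision),
            "macro_recall": r(self.macro_recall),
            "macro_f1": r(self.macro_f1),
            "weighted_precision": r(self.weighted_precision),
            "weighted_recall": r(self.weighted_recall),
            "weighted_f1": r(self.weighted_f1),
            "per_class": {
                str(cls_): {
                    "precision": r(row["precision"]),
                    "recall": r(row["recall"]),
                    "f1": r(row["f1"]),
                    "support": int(row["support"]),
                }
                for cls_, row in self.per_class.iterrows()
            },
            "confusion": {
                "labels": [str(c) for c in self.confusion.index],
                "counts": self.confusion.to_numpy().tolist(),
            },
        }

    def summary(self) -> str:
        nd = self.rounding
        lines = [
            f"samples: {int(self.confusion.to_numpy().sum())}"
            f"  classes: {len(self.per_class)}",
            f"accuracy: {round_display(self.accuracy, nd)}",
            "",
            self.per_class.round(nd).to_string(),
            "",
            f"macro    precision={round_display(self.macro_precision, nd)}"
            f" recall={round_display(self.macro_recall, nd)}"
            f" f1={round_display(self.macro_f1, nd)}",
            f"weighted precision={round_display(self.weighted_precision, nd)}"
            f" recall={round_display(self.weighted_recall, nd)}"
            f" f1={round_display(self.weighted_f1, nd)}",
        ]
        return "\n".join(lines)


def classification_report(confusion: pd.DataFrame, rounding: int = 4) -> EvaluationReport:
    """Per-class and aggregate metrics from a confusion count table."""
    counts = confusion.to_numpy(dtype=float)
    if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("confusion matrix entries must be nonnegative integers")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    support = counts.sum(axis=1)
    total = counts.sum()

    def _safe_div(num, den, what):
        out = np.zeros_like(num, dtype=float)
        zero = den == 0
        if np.any(zero):
            warnings.warn(
                f"zero denominator in {what} for class(es) "
                f"{[str(confusion.index[i]) for i in np.flatnonzero(zero)]}; "
                "reporting 0",
                RuntimeWarning,
                stacklevel=2,
            )
        np.divide(num, den, out=out, where=~zero)
        return out

    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(tp, tp + 0.5 * (fp + fn), "F1")
    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support.astype(int),
        },
        index=pd.Index(confusion.index, name="class"),
    )
    accuracy = float(tp.sum() / total) if total > 0 else 0.0
    if total == 0:
        macro = dict(precision=0.0, recall=0.0, f1=0.0)
        wavg = dict(precision=0.0, recall=0.0, f1=0.0)
    else:
        macro = {k: macro_average(per_class[k]) for k in ("precision", "recall", "f1")}
        wavg = {
            k: weighted_average(per_class[k], support) if support.sum() else 0.0
            for k in ("precision", "recall", "f1")
        }
    return EvaluationReport(
        confusion=confusion,
        per_class=per_class,
        accuracy=accuracy,
        macro_precision=macro["precision"],
        macro_recall=macro["recall"],
        macro_f1=macro["f1"],
        weighted_precision=wavg["precision"],
        weighted_recall=wavg["recall"],
        weighted_f1=wavg["f1"],
        rounding=rounding,
    )


def evaluate_predictions(truth, pred, class_labels, rounding: int = 4) -> EvaluationReport:
    """Convenience: confusion matrix + classification report in one call."""
    return classification_report(confusion_matrix(truth, pred, class_labels), rounding=rounding)


def roc_auc_ovr(class_scores, truth, class_labels) -> dict:
    """One-vs-rest ROC-AUC per class (rank statistic, ties counted half).

    Returns ``{"per_class": {label: auc-or-None}, "macro": mean over
    defined classes (None if none)}``. A class with no positives or no
    negatives is reported as ``None`` (undefined), never 0.
    """
    scores = np.asarray(class_scores, dtype=float)
    truth = np.asarray(list(truth), dtype=object)
    labels = list(class_labels)
    if scores.shape != (truth.size, len(labels)):
        raise ValueError("class_scores must have shape (n_samples, n_classes)")
    if not np.all(np.isfinite(scores)):
        raise ValueError("class scores must be finite")
    per_class: dict = {}
    for j, cls_ in enumerate(labels):
        y = (truth == cls_).astype(int)
        if y.sum() == 0 or y.sum() == y.size:
            per_class[cls_] = None
            continue
        per_class[cls_] = float(skm.roc_auc_score(y, scores[:, j]))
    defined = [v for v in per_class.values() if v is not None]
    macro = float(np.mean(defined)) if defined else None
    return {"per_class": per_class, "macro": macro}


@dataclass(frozen=True)
class McNemarResult:
    """Discordant counts and p-value of McNemar's paired test.

    ``b`` counts samples the first model got right and the second wrong;
    ``c`` the reverse. ``method`` is ``"exact"`` (doubled binomial tail,
    clamped at 1) for b+c < 25, ``"chi2_cc"`` (continuity-corrected
    chi-square) otherwise, or ``"degenerate"`` when b = c = 0.
    """

    b: int
    c: int
    statistic: float | None
    p_value: float
    method: str


def mcnemar_test(pred_a, pred_b, truth) -> McNemarResult:
    """McNemar's test on two classifiers' predictions of the same samples."""
    pred_a = np.asarray(list(pred_a), dtype=object)
    pred_b = np.asarray(list(pred_b), dtype=object)
    truth = np.asarray(list(truth), dtype=object)
    if not (pred_a.shape == pred_b.shape == truth.shape):
        raise ValueError("pred_a, pred_b and truth must have equal lengths")
    correct_a = pred_a == truth
    correct_b = pred_b == truth
    b = int(np.sum(correct_a & ~correct_b))
    c = int(np.sum(~correct_a & correct_b))
    n = b + c
    if n == 0:
        return McNemarResult(b=b, c=c, statistic=None, p_value=1.0, method="degenerate")
    if n < MCNEMAR_EXACT_THRESHOLD:
        p = min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n, 0.5)))
        return McNemarResult(b=b, c=c, statistic=None, p_value=p, method="exact")
    stat = (abs(b - c) - 1.0) ** 2 / n
    p = float(stats.chi2.sf(stat, df=1))
    return McNemarResult(b=b, c=c, statistic=stat, p_value=p, method="chi2_cc")
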