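"""Classifier evaluation: confusion tables, sensitivity/specificity, ROC and AUC.

Confusion tables follow the reporting layout used in clinical methylation
panels: rows are *predicted* classes, columns are *true* classes, followed by
summary rows (Totals, Correct, False positive, False negative, Specificity,
Sensitivity).  Per-class metrics are one-vs-rest:

    sensitivity_k = correct_k / total_k            (true-positive rate)
    specificity_k = TN_k / (TN_k + FP_k)           (true-negative rate)

where ``FP_k`` counts samples of other classes predicted as ``k``.
Percentages are rendered with half-up rounding to one decimal; full
precision is retained on the object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionTable",
    "ROCResult",
    "confusion_metrics",
    "roc_curve",
    "auc",
]


def round_half_up(x, decimals: int = 1):
    """Round half away from zero (the convention of printed clinical tables)."""
    factor = 10.0**decimals
    x = np.asarray(x, dtype=float)
    return np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)


@dataclass
class ConfusionTable:
    """Multi-class confusion counts with one-vs-rest summary metrics.

    ``counts`` is a square DataFrame with predicted classes as rows and true
    classes as columns.
    """

    classes: list[str]
    counts: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        """Per-class number of true samples (column sums)."""
        return self.counts.sum(axis=0)

    @property
    def correct(self) -> pd.Series:
        return pd.Series(np.diag(self.counts.values), index=self.classes)

    @property
    def false_positive(self) -> pd.Series:
        """Samples of other classes predicted as class k (row sum minus diagonal)."""
        return self.counts.sum(axis=1) - self.correct

    @property
    def false_negative(self) -> pd.Series:
        """Samples of class k predicted as something else."""
        return self.totals - self.correct

    @property
    def sensitivity(self) -> pd.Series:
        """Per-class true-positive rate, in percent (full precision)."""
        return 100.0 * self.correct / self.totals

    @property
    def specificity(self) -> pd.Series:
        """Per-class true-negative rate, in percent (full precision)."""
        n = self.counts.values.sum()
        tn = n - self.totals - self.false_positive
        return 100.0 * tn / (tn + self.false_positive)

    @property
    def accuracy(self) -> float:
        return float(self.correct.sum() / self.counts.values.sum())

    def error_taxonomy(self, normal_label: str = "normal") -> dict[str, int]:
        """Count the three clinically distinct error types.

        ``false_negative``: a disease sample called ``normal_label``;
        ``false_positive``: a normal sample called disease;
        ``wrong_type``: a disease sample called a *different* disease.
        When ``normal_label`` is absent every off-diagonal cell is a
        ``wrong_type`` call.
        """
        fn = fp = wrong = 0
        for pred in self.classes:
            for true in self.classes:
                if pred == true:
                    continue
                c = int(self.counts.loc[pred, true])
                if pred == normal_label:
                    fn += c
                elif true == normal_label:
                    fp += c
                else:
                    wrong += c
        return {"false_negative": fn, "false_positive": fp, "wrong_type": wrong}

    def render(self) -> pd.DataFrame:
        """Report-style table: predicted-class rows then summary rows."""
        rows = {c: self.counts.loc[c] for c in self.classes}
        rows["Totals"] = self.totals
        rows["Correct"] = self.correct
        rows["False positive"] = self.false_positive
        rows["False negative"] = self.false_negative
        rows["Specificity (%)"] = pd.Series(
            round_half_up(self.specificity.values), index=self.classes
        )
        rows["Sensitivity (%)"] = pd.Series(
            round_half_up(self.sensitivity.values), index=self.classes
        )
        return pd.DataFrame(rows).T[self.classes]

    def to_tsv(self, path) -> None:
        self.render().to_csv(path, sep="\t")


def confusion_metrics(
    true_labels,
    predicted_labels,
    positive_class: str | None = None,
    classes: list[str] | None = None,
) -> ConfusionTable:
    """Build a :class:`ConfusionTable` from paired label vectors.

    ``positive_class``, when given, is placed first in the class ordering so
    reports read case-then-control.  ``classes`` may widen the label universe
    (e.g. a model's classes); labels outside it raise ``ValueError``.
    """
    true_labels = pd.Series(list(true_labels))
    predicted_labels = pd.Series(list(predicted_labels))
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors must have equal length")
    if classes is None:
        classes = sorted(set(true_labels) | set(predicted_labels))
    else:
        classes = list(classes)
        seen = set(true_labels) | set(predicted_labels)
        unknown = seen - set(classes)
        if unknown:
            raise ValueError(f"labels outside the model classes: {sorted(unknown)}")
    if positive_class is not None:
        if positive_class not in classes:
            raise ValueError(f"positive_class {positive_class!r} not among classes")
        classes = [positive_class] + [c for c in classes if c != positive_class]
    counts = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        counts.loc[p, t] += 1
    return ConfusionTable(classes=classes, counts=counts)


@dataclass
class ROCResult:
    """ROC sweep: thresholds (descending score cut-points), FPR/TPR and AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        )


def roc_curve(scores, binary_labels) -> ROCResult:
    """ROC over all score thresholds, ties grouped into single steps.

    The trapezoid AUC of the resulting polyline equals the Mann-Whitney
    statistic U/(n1*n0) with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(binary_labels).astype(bool)
    if y.all() or (~y).all():
        raise ValueError("both classes must be present to compute a ROC curve")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    yy = y[order]
    # group tied scores into one threshold step
    distinct = np.r_[True, np.diff(s) != 0]
    boundaries = np.r_[np.flatnonzero(distinct)[1:], len(s)]
    tp = np.cumsum(yy)[boundaries - 1]
    fp = np.cumsum(~yy)[boundaries - 1]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thresholds = np.r_[np.inf, s[distinct]]
    area = float(np.trapezoid(tpr, fpr))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=area)


def auc(scores, binary_labels) -> float:
    """Trapezoid area under the ROC curve (equals U/(n1*n0), ties half)."""
    return roc_curve(scores, binary_labels).auc
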