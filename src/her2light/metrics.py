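"""HER2 label-grouping schemes and the evaluation metric suite.

HER2 immunohistochemistry scores (0, 1+, 2+, 3+) are evaluated under three
groupings: four-class (identity), three-class (negative = {0, 1+},
borderline = 2+, positive = 3+) and binary (negative = {0, 1+} vs
positive = 3+, with the equivocal 2+ cases excluded).  Reports carry the
confusion matrix, accuracy, macro precision/recall/F1, AUC (one-vs-rest
macro for more than two classes) and the Matthews correlation coefficient.
Accuracy/precision/recall/F1/AUC are reported in percent, matching the
convention of the published tables; MCC stays on its natural [-1, 1] scale.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import (confusion_matrix as _sk_confusion,
                             precision_recall_fscore_support, roc_auc_score)

__all__ = [
    "LabelScheme", "SCHEMES", "MetricsReport", "group_labels",
    "confusion_and_summary", "mcc", "plot_confusion_matrix",
]

EXCLUDED = -1
_SCORE_ALIASES = {"0": "0", "1+": "1+", "2+": "2+", "3+": "3+",
                  "1": "1+", "2": "2+", "3": "3+"}


@dataclass(frozen=True)
class LabelScheme:
    name: str
    mapping: dict  # HER2 score string -> class index or EXCLUDED
    class_names: tuple

    @property
    def num_classes(self) -> int:
        return len(self.class_names)


SCHEMES = {
    "four_class": LabelScheme(
        "four_class",
        {"0": 0, "1+": 1, "2+": 2, "3+": 3},
        ("0", "1+", "2+", "3+")),
    "three_class": LabelScheme(
        "three_class",
        {"0": 0, "1+": 0, "2+": 1, "3+": 2},
        ("negative", "borderline", "positive")),
    "binary": LabelScheme(
        "binary",
        {"0": 0, "1+": 0, "2+": EXCLUDED, "3+": 1},
        ("negative", "positive")),
}


def _normalize_score(s) -> str:
    key = str(s).strip()
    if key not in _SCORE_ALIASES:
        raise ValueError(f"unknown HER2 score {s!r}; expected one of 0, 1+, 2+, 3+")
    return _SCORE_ALIASES[key]


def group_labels(scores, scheme) -> tuple[np.ndarray, np.ndarray]:
    """Map HER2 scores to class labels under a scheme.

    Returns ``(labels, mask)`` where ``mask`` marks the samples kept
    (excluded scores, e.g. 2+ under the binary scheme, are dropped).
    """
    if isinstance(scheme, str):
        scheme = SCHEMES[scheme]
    mapped = np.array([scheme.mapping[_normalize_score(s)] for s in scores], dtype=int)
    mask = mapped != EXCLUDED
    return mapped[mask], mask


@dataclass
class MetricsReport:
    confusion: np.ndarray
    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None
    mcc: float
    per_class: pd.DataFrame
    class_names: tuple = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "confusion_matrix": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "mcc": self.mcc,
            "per_class": self.per_class.to_dict(orient="list"),
            "class_names": list(self.class_names),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary_row(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1, "auc": self.auc,
                "mcc": self.mcc}


def mcc(y_true, y_pred) -> float:
    """Matthews correlation coefficient (multiclass covariance form); a
    degenerate zero denominator yields 0 by convention."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if y_true.size == 0:
        raise ValueError("mcc needs at least one sample")
    k = int(max(y_true.max(), y_pred.max())) + 1
    cm = np.zeros((k, k), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    t = cm.sum(axis=1).astype(float)  # true counts per class
    p = cm.sum(axis=0).astype(float)  # predicted counts per class
    n = cm.sum()
    c = np.trace(cm)
    cov_tp = c * n - t @ p
    denom = math.sqrt(n * n - p @ p) * math.sqrt(n * n - t @ t)
    if denom == 0:
        return 0.0
    return float(cov_tp / denom)


def confusion_and_summary(y_true, y_prob, class_names=None) -> MetricsReport:
    """Full metric report from true labels and predicted probabilities.

    ``y_prob`` is (N, K) softmax rows or an (N,)/(N, 1) sigmoid column.
    Predictions use argmax (0.5 threshold for the sigmoid column).  Macro
    averaging is used for multiclass precision/recall/F1 and AUC.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_prob.ndim == 1:
        y_prob = y_prob[:, None]
    if y_prob.shape[1] == 1:
        k = 2
        y_pred = (y_prob[:, 0] >= 0.5).astype(int)
        prob_pos = y_prob[:, 0]
    else:
        k = y_prob.shape[1]
        y_pred = y_prob.argmax(axis=1)
        prob_pos = None
    labels = np.arange(k)
    cm = _sk_confusion(y_true, y_pred, labels=labels)
    accuracy = float(np.trace(cm) / cm.sum())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0)
    pc_prec, pc_rec, pc_f1, pc_support = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average=None, zero_division=0)
    per_class = pd.DataFrame({
        "class": class_names if class_names is not None else [str(c) for c in labels],
        "precision": pc_prec, "recall": pc_rec, "f1": pc_f1,
        "support": pc_support,
    })
    auc = None
    if len(np.unique(y_true)) < 2:
        warnings.warn("AUC undefined for single-class y_true; reported as None")
    elif k == 2:
        auc = float(roc_auc_score(y_true, prob_pos if prob_pos is not None
                                  else y_prob[:, 1])) * 100.0
    else:
        try:
            auc = float(roc_auc_score(y_true, y_prob, multi_class="ovr",
                                      average="macro", labels=labels)) * 100.0
            if math.isnan(auc):  # some class absent from y_true
                warnings.warn("AUC undefined: a class is absent from y_true")
                auc = None
        except ValueError as e:
            warnings.warn(f"AUC not computable: {e}")
    return MetricsReport(
        confusion=cm,
        accuracy=accuracy * 100.0,
        precision=float(prec) * 100.0,
        recall=float(rec) * 100.0,
        f1=float(f1) * 100.0,
        auc=auc,
        mcc=mcc(y_true, y_pred),
        per_class=per_class,
        class_names=tuple(per_class["class"]),
    )


def plot_confusion_matrix(report: MetricsReport, path=None, title=""):
    """Labelled confusion-matrix heat map (matplotlib figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cm = report.confusion
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(cm, cmap="Blues")
    names = report.class_names or [str(i) for i in range(len(cm))]
    ax.set_xticks(range(len(cm)), names)
    ax.set_yticks(range(len(cm)), names)
    ax.set_xlabel("Predicted")
    ax.set_ylabel("True")
    if title:
        ax.set_title(title)
    for i in range(len(cm)):
        for j in range(len(cm)):
            ax.text(j, i, str(cm[i, j]), ha="center", va="center",
                    color="white" if cm[i, j] > cm.max() / 2 else "black")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
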