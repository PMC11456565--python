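"""Classifier evaluation: accuracy, macro precision/recall/F1, ROC/AUC.

Macro averaging is used throughout (each load class contributes equally), and
macro-F1 is the headline metric — with three unbalanced turn classes it is
the most honest single number.  ROC analysis for the 3-class problem is
one-vs-rest, one curve and AUC per class plus their macro mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support

CLASSES = (1, 2, 3)


@dataclass
class EvaluationReport:
    model_name: str
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class_auc: tuple[float, float, float]
    macro_auc: float
    confusion: np.ndarray
    n_test: int

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc_climbing": self.per_class_auc[0],
            "auc_leveling": self.per_class_auc[1],
            "auc_descending": self.per_class_auc[2],
            "macro_auc": self.macro_auc,
            "n_test": self.n_test,
        }


def roc_curve(y_true, scores):
    """One-vs-rest ROC by threshold sweep.

    ``y_true`` is binary (1 = positive).  Ties in ``scores`` move both
    coordinates in one step.  Returns (fpr, tpr) arrays starting at (0, 0)
    and ending at (1, 1), both monotone non-decreasing.
    """
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if not (y.any() and (~y).any()):
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    y, s = y[order], s[order]
    tps = np.cumsum(y)
    fps = np.cumsum(~y)
    # keep only the last point of each tied-score block
    last = np.r_[np.flatnonzero(np.diff(s)), y.size - 1]
    tpr = np.r_[0.0, tps[last] / tps[-1]]
    fpr = np.r_[0.0, fps[last] / fps[-1]]
    return fpr, tpr


def auc_trapezoid(fpr, tpr) -> float:
    return float(np.trapezoid(tpr, fpr))


def auc_pair_count(y_true, scores) -> float:
    """Mann–Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie), by enumeration."""
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y], s[~y]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return float(wins / (pos.size * neg.size))


def classification_metrics(y_true, y_prob, model_name: str = "model") -> EvaluationReport:
    """Full report from per-class probabilities (argmax decision rule)."""
    y_true = np.asarray(y_true, int)
    y_prob = np.asarray(y_prob, float)
    if y_prob.ndim != 2 or y_prob.shape[1] != len(CLASSES):
        raise ValueError("y_prob must be (n, 3)")
    y_pred = y_prob.argmax(axis=1) + 1
    conf = confusion_matrix(y_true, y_pred, labels=list(CLASSES))
    acc = float(np.trace(conf) / conf.sum())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=list(CLASSES), average="macro", zero_division=0
    )
    aucs = []
    for k, c in enumerate(CLASSES):
        binary = y_true == c
        if binary.all() or not binary.any():
            aucs.append(float("nan"))
            continue
        aucs.append(auc_trapezoid(*roc_curve(binary, y_prob[:, k])))
    finite = [a for a in aucs if np.isfinite(a)]
    return EvaluationReport(
        model_name=model_name,
        accuracy=acc,
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        per_class_auc=tuple(aucs),
        macro_auc=float(np.mean(finite)) if finite else float("nan"),
        confusion=conf,
        n_test=int(y_true.size),
    )


def compare_models(reports: list[EvaluationReport]) -> pd.DataFrame:
    """Rank models by macro-F1 (ties broken by macro AUC)."""
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to compare")
    rows = sorted(reports, key=lambda r: (-r.f1, -r.macro_auc))
    return pd.DataFrame([r.to_dict() for r in rows])
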