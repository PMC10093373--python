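"""Evaluation protocol: stratified 70/30 split, confusion matrix, and
per-class + macro accuracy / sensitivity / specificity / F-score / MCC.

Per-class metrics use the one-vs-rest convention: class k is the positive
class, all others pooled as negative.  Any metric whose denominator is zero
is defined as 0.  The macro row is the unweighted mean over classes.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib

import numpy as np
import pandas as pd

__all__ = ["EvaluationReport", "stratified_split", "confusion",
           "per_class_metrics", "macro_report"]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "fscore", "mcc")


@dataclasses.dataclass
class EvaluationReport:
    confusion_matrix: np.ndarray
    per_class: pd.DataFrame          # one row per class, METRIC_NAMES columns
    macro: dict[str, float]          # unweighted means

    def to_frame(self, scale: float = 100.0) -> pd.DataFrame:
        """Table layout on the 0-100 display scale with an 'average' row."""
        rows = self.per_class.copy() * scale
        rows.insert(0, "class", self.per_class.index.astype(str))
        avg = {"class": "average"}
        avg.update({k: v * scale for k, v in self.macro.items()})
        return pd.concat([rows, pd.DataFrame([avg])], ignore_index=True).round(2)

    def to_csv(self, path: str | pathlib.Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path: str | pathlib.Path | None = None) -> str:
        payload = {
            "confusion_matrix": self.confusion_matrix.tolist(),
            "per_class": {str(k): {m: float(self.per_class.loc[k, m])
                                   for m in METRIC_NAMES}
                          for k in self.per_class.index},
            "macro": {m: float(v) for m, v in self.macro.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            pathlib.Path(path).write_text(text)
        return text


def stratified_split(labels: np.ndarray, train_fraction: float = 0.70,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Index split preserving class proportions.

    Per-class training counts are floored, then the remaining slots (to reach
    round(N * train_fraction) in total) go to the classes with the largest
    fractional remainders; remainder ties favour the larger class.
    Returns (train_indices, test_indices).
    """
    labels = np.asarray(labels)
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 samples to split")
    exact = counts * train_fraction
    take = np.floor(exact).astype(int)
    short = int(round(labels.size * train_fraction)) - int(take.sum())
    if short > 0:
        frac = exact - np.floor(exact)
        order = sorted(range(len(classes)),
                       key=lambda i: (-frac[i], -counts[i], i))
        for i in order[:short]:
            take[i] += 1
    take = np.clip(take, 1, counts - 1)  # both folds see every class

    rng = np.random.default_rng(seed)
    train_idx, test_idx = [], []
    for cls, n_train in zip(classes, take):
        idx = np.flatnonzero(labels == cls)
        idx = rng.permutation(idx)
        train_idx.append(idx[:n_train])
        test_idx.append(idx[n_train:])
    return (np.sort(np.concatenate(train_idx)),
            np.sort(np.concatenate(test_idx)))


def confusion(y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
              ) -> np.ndarray:
    """K×K count matrix; rows are true classes, columns predictions."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label arrays must have equal length")
    if y_true.size and (min(y_true.min(), y_pred.min()) < 0
                        or max(y_true.max(), y_pred.max()) >= n_classes):
        raise ValueError("labels out of range")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def per_class_metrics(cm: np.ndarray, k: int) -> dict[str, float]:
    """One-vs-rest metrics for class k from the full confusion matrix."""
    cm = np.asarray(cm)
    total = cm.sum()
    tp = cm[k, k]
    fn = cm[k, :].sum() - tp
    fp = cm[:, k].sum() - tp
    tn = total - tp - fn - fp
    mcc_den = math.sqrt(float((tp + fp)) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "accuracy": _safe_div(tp + tn, total),
        "sensitivity": _safe_div(tp, tp + fn),
        "specificity": _safe_div(tn, tn + fp),
        "fscore": _safe_div(2 * tp, 2 * tp + fp + fn),
        "mcc": _safe_div(float(tp) * tn - float(fp) * fn, mcc_den),
    }


def macro_report(cm: np.ndarray) -> EvaluationReport:
    """Per-class table plus unweighted macro averages."""
    cm = np.asarray(cm)
    rows = {k: per_class_metrics(cm, k) for k in range(cm.shape[0])}
    per_class = pd.DataFrame.from_dict(rows, orient="index")[list(METRIC_NAMES)]
    macro = {m: float(per_class[m].mean()) for m in METRIC_NAMES}
    return EvaluationReport(confusion_matrix=cm, per_class=per_class, macro=macro)
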