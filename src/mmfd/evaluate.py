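"""Confusion matrices and per-class/macro/weighted classification reports.

Per-class metrics are one-vs-rest: ``precision = TP / (TP + FP)``,
``recall = TP / (TP + FN)``, ``F1 = 2 * P * R / (P + R)``, each defined as 0
when its denominator vanishes (flagged, never an exception).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EvalReport", "confusion", "row_normalize", "metrics", "report"]


@dataclass
class EvalReport:
    confusion: np.ndarray  # K x K counts, entry (i, j) = true i predicted j
    confusion_pct: np.ndarray  # row-normalized to percentages
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    accuracy: float
    macro: dict[str, float]
    weighted: dict[str, float]
    zero_division_flags: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "confusion_pct": self.confusion_pct.tolist(),
            "per_class": {
                str(c): {
                    "precision": float(self.precision[c]),
                    "recall": float(self.recall[c]),
                    "f1": float(self.f1[c]),
                    "support": int(self.support[c]),
                }
                for c in range(len(self.precision))
            },
            "accuracy": self.accuracy,
            "macro": self.macro,
            "weighted": self.weighted,
            "zero_division_flags": self.zero_division_flags,
        }

    def render(self) -> str:
        """Aligned text table: per-class precision/recall/F1, macro avg, accuracy."""
        lines = [f"{'Class':>10} {'Precision':>10} {'Recall':>10} {'F1-score':>10} {'Support':>10}"]
        for c in range(len(self.precision)):
            lines.append(
                f"{c:>10} {self.precision[c]:>10.4f} {self.recall[c]:>10.4f} "
                f"{self.f1[c]:>10.4f} {self.support[c]:>10d}"
            )
        lines.append(
            f"{'Macro Avg':>10} {self.macro['precision']:>10.4f} "
            f"{self.macro['recall']:>10.4f} {self.macro['f1']:>10.4f} {self.n:>10d}"
        )
        lines.append(
            f"{'Wtd Avg':>10} {self.weighted['precision']:>10.4f} "
            f"{self.weighted['recall']:>10.4f} {self.weighted['f1']:>10.4f} {self.n:>10d}"
        )
        lines.append(f"{'Accuracy':>10} {self.accuracy:>10.4f}")
        return "\n".join(lines)


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K count matrix; entry (i, j) counts true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("label length mismatch")
    if y_true.size and (
        y_true.min() < 0 or y_true.max() >= n_classes or y_pred.min() < 0 or y_pred.max() >= n_classes
    ):
        raise ValueError(f"labels outside [0, {n_classes})")
    mat = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(mat, (y_true, y_pred), 1)
    return mat


def row_normalize(mat: np.ndarray) -> np.ndarray:
    """100 * row / rowsum; empty rows become zeros."""
    mat = np.asarray(mat, dtype=float)
    sums = mat.sum(axis=1, keepdims=True)
    out = np.zeros_like(mat)
    np.divide(100.0 * mat, sums, out=out, where=sums > 0)
    return out


def metrics(confusion_matrix: np.ndarray) -> EvalReport:
    """Per-class one-vs-rest precision/recall/F1 plus macro/weighted averages."""
    mat = np.asarray(confusion_matrix)
    if mat.size == 0 or mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("confusion matrix must be square and non-empty")
    K = mat.shape[0]
    n = mat.sum()
    tp = np.diag(mat).astype(float)
    fp = mat.sum(axis=0) - tp
    fn = mat.sum(axis=1) - tp
    support = mat.sum(axis=1)

    flags: list[str] = []
    precision = np.zeros(K)
    recall = np.zeros(K)
    f1 = np.zeros(K)
    for c in range(K):
        if tp[c] + fp[c] > 0:
            precision[c] = tp[c] / (tp[c] + fp[c])
        else:
            flags.append(f"class {c}: precision 0/0")
        if tp[c] + fn[c] > 0:
            recall[c] = tp[c] / (tp[c] + fn[c])
        else:
            flags.append(f"class {c}: recall 0/0")
        if precision[c] + recall[c] > 0:
            f1[c] = 2 * precision[c] * recall[c] / (precision[c] + recall[c])
        else:
            flags.append(f"class {c}: F1 0/0")

    accuracy = float(tp.sum() / n) if n > 0 else 0.0
    weights = support / n if n > 0 else np.zeros(K)
    macro = {
        "precision": float(precision.mean()),
        "recall": float(recall.mean()),
        "f1": float(f1.mean()),
    }
    weighted = {
        "precision": float((precision * weights).sum()),
        "recall": float((recall * weights).sum()),
        "f1": float((f1 * weights).sum()),
    }
    return EvalReport(
        confusion=mat.astype(int),
        confusion_pct=row_normalize(mat),
        precision=precision,
        recall=recall,
        f1=f1,
        support=support.astype(int),
        accuracy=accuracy,
        macro=macro,
        weighted=weighted,
        zero_division_flags=flags,
    )


def report(trained, dataset) -> EvalReport:
    """Evaluate a trained model on a feature dataset (eval mode, deterministic)."""
    from mmfd.model import predict

    if len(dataset) == 0:
        raise ValueError("empty dataset")
    model = getattr(trained, "model", trained)
    y_pred = predict(model, dataset)
    mat = confusion(dataset.y, y_pred, model.config.n_classes)
    return metrics(mat)
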