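"""Confusion-matrix metrics, fold aggregation, and the F1-range balance statistic.

Per class c of a K x K confusion matrix (rows = true, columns = predicted):

    TP = cm[c, c]            FN = row c sum  - TP
    FP = column c sum - TP   precision = TP / (TP + FP)
    recall = TP / (TP + FN)  F1 = 2 P R / (P + R)
    accuracy = trace / total

Undefined ratios (empty denominators) are reported as NaN — an explicit
"undefined" marker — never silently coerced to 0.

Cross-validated results are aggregated the way published prediction matrices
are: the primary report arithmetically averages each per-fold metric *value*;
metrics recomputed from the pooled (summed) confusion matrix are emitted
alongside under a separate key, since the two conventions genuinely differ.
The balance statistic ``f1_range`` is max - min of the fold-averaged
per-class F1 scores: small values mean no species lags the others.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "ClassMetrics",
    "FoldReport",
    "confusion",
    "class_metrics",
    "aggregate_folds",
    "compare_reports",
    "f1_score",
    "format_report",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (K, K) ints, rows = true class
    labels: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or c.shape[0] != len(self.labels):
            raise ValueError(f"counts must be KxK with K={len(self.labels)}, got {c.shape}")
        if (c < 0).any():
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(np.asarray(self.counts).sum())


@dataclass(frozen=True)
class ClassMetrics:
    labels: tuple[str, ...]
    precision: np.ndarray  # per class; NaN where undefined
    recall: np.ndarray
    f1: np.ndarray
    accuracy: float

    def as_dict(self) -> dict:
        def clean(v):
            return None if np.isnan(v) else float(v)

        return {
            "labels": list(self.labels),
            "precision": [clean(v) for v in self.precision],
            "recall": [clean(v) for v in self.recall],
            "f1": [clean(v) for v in self.f1],
            "accuracy": float(self.accuracy),
        }


def confusion(y_true, y_pred, labels) -> ConfusionMatrix:
    """Tally counts[i, j] = #{samples with true label i predicted as j}."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    labels = tuple(labels)
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            unknown = t if t not in index else p
            raise ValueError(f"label {unknown!r} not in label set {list(labels)}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, labels)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; NaN if either is undefined or
    both are zero."""
    if np.isnan(precision) or np.isnan(recall) or (precision + recall) == 0:
        return float("nan")
    return 2.0 * precision * recall / (precision + recall)


def class_metrics(cm: ConfusionMatrix) -> ClassMetrics:
    """Per-class precision/recall/F1 and overall accuracy from a confusion
    matrix; empty denominators yield NaN."""
    counts = np.asarray(cm.counts, dtype=np.float64)
    if counts.sum() == 0:
        raise ValueError("confusion matrix is empty: no evaluated samples")
    tp = np.diag(counts)
    fp = counts.sum(axis=0) - tp
    fn = counts.sum(axis=1) - tp
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / (tp + fp), np.nan)
        recall = np.where(tp + fn > 0, tp / (tp + fn), np.nan)
    f1 = np.array([f1_score(p, r) for p, r in zip(precision, recall)])
    accuracy = float(tp.sum() / counts.sum())
    return ClassMetrics(cm.labels, precision, recall, f1, accuracy)


@dataclass(frozen=True)
class FoldReport:
    """Per-fold metrics plus their arithmetic fold-average.

    ``pooled`` holds metrics recomputed from the summed confusion matrix when
    the per-fold matrices are available (the alternative aggregation
    convention), else None.  ``f1_range`` is max - min of the averaged
    per-class F1 values.
    """

    per_fold: tuple[ClassMetrics, ...]
    averaged: ClassMetrics
    f1_range: float
    pooled: ClassMetrics | None = None

    def as_dict(self) -> dict:
        return {
            "per_fold": [m.as_dict() for m in self.per_fold],
            "averaged": self.averaged.as_dict(),
            "f1_range": float(self.f1_range),
            "pooled": self.pooled.as_dict() if self.pooled is not None else None,
        }


def _nanmean_strict(stack: np.ndarray) -> np.ndarray:
    # mean over folds; a cell undefined in any fold stays undefined
    return stack.mean(axis=0)


def aggregate_folds(
    reports: list[ClassMetrics], matrices: list[ConfusionMatrix] | None = None
) -> FoldReport:
    """Fold-average per-class metrics and compute the F1-range balance statistic.

    Every cell of the averaged report is the arithmetic mean of that cell over
    folds.  If the per-fold confusion matrices are supplied, metrics from the
    summed matrix are attached as ``pooled`` for comparison.
    """
    if not reports:
        raise ValueError("need at least one fold report")
    labels = reports[0].labels
    for r in reports[1:]:
        if r.labels != labels:
            raise ValueError(f"label sets differ across folds: {r.labels} vs {labels}")
    averaged = ClassMetrics(
        labels,
        _nanmean_strict(np.stack([r.precision for r in reports])),
        _nanmean_strict(np.stack([r.recall for r in reports])),
        _nanmean_strict(np.stack([r.f1 for r in reports])),
        float(np.mean([r.accuracy for r in reports])),
    )
    f1_range = float(np.nanmax(averaged.f1) - np.nanmin(averaged.f1))
    pooled = None
    if matrices:
        if any(m.labels != labels for m in matrices):
            raise ValueError("confusion-matrix label sets differ from report labels")
        summed = ConfusionMatrix(
            np.sum([np.asarray(m.counts) for m in matrices], axis=0), labels
        )
        pooled = class_metrics(summed)
    return FoldReport(tuple(reports), averaged, f1_range, pooled)


def compare_reports(a: FoldReport | ClassMetrics, b: FoldReport | ClassMetrics) -> dict:
    """Cell-wise differences a - b, as proportions and percentage points."""
    ma = a.averaged if isinstance(a, FoldReport) else a
    mb = b.averaged if isinstance(b, FoldReport) else b
    if ma.labels != mb.labels:
        raise ValueError(f"label sets differ: {ma.labels} vs {mb.labels}")
    out: dict = {"labels": list(ma.labels)}
    for name in ("precision", "recall", "f1"):
        delta = getattr(ma, name) - getattr(mb, name)
        out[name] = {
            "proportion": [None if np.isnan(v) else float(v) for v in delta],
            "percentage_points": [None if np.isnan(v) else float(100 * v) for v in delta],
        }
    acc = ma.accuracy - mb.accuracy
    out["accuracy"] = {"proportion": float(acc), "percentage_points": float(100 * acc)}
    return out


def format_report(report: FoldReport, decimals: int = 3) -> str:
    """Render a fold-averaged report as an aligned prediction-matrix table."""
    m = report.averaged
    width = max(8, max(len(l) for l in m.labels) + 2)

    def row(name, values):
        cells = "".join(
            f"{('nan' if np.isnan(v) else format(v, f'.{decimals}f')):>{width}}" for v in values
        )
        return f"{name:<12}{cells}"

    lines = [
        f"{'':<12}" + "".join(f"{lab:>{width}}" for lab in m.labels),
        row("Precision", m.precision),
        row("Recall", m.recall),
        row("F1-Score", m.f1),
        f"{'Accuracy':<12}{m.accuracy:.{decimals}f}",
        f"{'F1 range':<12}{report.f1_range:.{decimals}f}",
    ]
    return "\n".join(lines)
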