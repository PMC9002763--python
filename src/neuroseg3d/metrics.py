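"""Per-structure segmentation evaluation: Dice, precision, recall, IoU.

Each structure is evaluated one-vs-rest on voxel counts: the prediction and
ground truth are binarised at the class ID and

* precision = TP / (TP + FP)
* recall    = TP / (TP + FN)
* Dice      = 2·TP / (2·TP + FP + FN)  (harmonic mean of the two)
* IoU       = TP / (TP + FP + FN), related by IoU = Dice / (2 − Dice).

A class empty in both volumes scores 1.0 by convention and is flagged.
A report carries per-structure rows plus two summary rows: the **macro
average** (unweighted mean over structures, background excluded) and the
**support-weighted average** (weighted by ground-truth voxel count, with
background included by default — the convention under which a dominant
near-perfect background can raise the weighted mean above every individual
structure).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_nifti import LabelVolume

__all__ = ["ConfusionCounts", "MetricsReport", "confusion", "confusion_all",
           "dice", "precision", "recall", "iou", "report", "report_from_counts"]


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest voxel counts for a single class."""

    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def support(self) -> int:
        return self.tp + self.fn


def _as_array(vol) -> np.ndarray:
    return vol.voxels if isinstance(vol, LabelVolume) else np.asarray(vol)


def confusion(pred, truth, class_id: int) -> ConfusionCounts:
    """Exact TP/FP/FN counts for one class."""
    p = _as_array(pred) == class_id
    t = _as_array(truth) == class_id
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    tp = int(np.count_nonzero(p & t))
    return ConfusionCounts(tp=tp,
                           fp=int(np.count_nonzero(p)) - tp,
                           fn=int(np.count_nonzero(t)) - tp)


def confusion_all(pred, truth, n_classes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-class (tp, fp, fn) arrays via the full confusion matrix."""
    p = _as_array(pred).ravel()
    t = _as_array(truth).ravel()
    if p.shape != t.shape:
        raise ValueError("shape mismatch between prediction and truth")
    if p.max(initial=0) >= n_classes or t.max(initial=0) >= n_classes:
        raise ValueError("label ID outside 0..n_classes-1")
    cm = np.bincount(t.astype(np.int64) * n_classes + p.astype(np.int64),
                     minlength=n_classes * n_classes).reshape(n_classes, n_classes)
    tp = np.diag(cm)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    return tp, fp, fn


def dice(c: ConfusionCounts) -> float:
    den = 2 * c.tp + c.fp + c.fn
    return 1.0 if den == 0 else 2.0 * c.tp / den


def precision(c: ConfusionCounts) -> float:
    if c.tp + c.fp == 0:
        return 1.0 if c.fn == 0 else 0.0
    return c.tp / (c.tp + c.fp)


def recall(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        return 1.0 if c.fp == 0 else 0.0
    return c.tp / (c.tp + c.fn)


def iou(c: ConfusionCounts) -> float:
    den = c.tp + c.fp + c.fn
    return 1.0 if den == 0 else c.tp / den


@dataclass
class MetricsReport:
    """Per-structure metrics plus macro and support-weighted summary rows."""

    class_ids: np.ndarray          # structure IDs 1..S
    precision: np.ndarray
    recall: np.ndarray
    dice: np.ndarray
    iou: np.ndarray
    support: np.ndarray            # ground-truth voxels per structure
    both_empty: np.ndarray         # convention flag per structure
    macro_average: dict[str, float]
    weighted_average: dict[str, float]

    def to_tsv(self) -> str:
        lines = ["Structure\tPrecision\tRecall\tDice\tIoU\tSupport"]
        for i, cid in enumerate(self.class_ids):
            lines.append(f"{cid}\t{self.precision[i]:.4f}\t{self.recall[i]:.4f}"
                         f"\t{self.dice[i]:.4f}\t{self.iou[i]:.4f}\t{self.support[i]}")
        for name, row in (("Macro average", self.macro_average),
                          ("Weighted average", self.weighted_average)):
            lines.append(f"{name}\t{row['precision']:.4f}\t{row['recall']:.4f}"
                         f"\t{row['dice']:.4f}\t{row['iou']:.4f}\t")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "per_class": [
                {"class_id": int(cid), "precision": float(self.precision[i]),
                 "recall": float(self.recall[i]), "dice": float(self.dice[i]),
                 "iou": float(self.iou[i]), "support": int(self.support[i]),
                 "both_empty": bool(self.both_empty[i])}
                for i, cid in enumerate(self.class_ids)],
            "macro_average": self.macro_average,
            "weighted_average": self.weighted_average,
        }

    def save(self, path) -> None:
        """Write ``<stem>.tsv`` and ``<stem>.json`` next to each other."""
        path = Path(path)
        path.with_suffix(".tsv").write_text(self.to_tsv())
        path.with_suffix(".json").write_text(json.dumps(self.to_dict(), indent=2))


def _metrics_from(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray):
    tp, fp, fn = (a.astype(np.float64) for a in (tp, fp, fn))
    both_empty = (tp + fp + fn) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), np.where(fn == 0, 1.0, 0.0))
        rec = np.where(tp + fn > 0, tp / (tp + fn), np.where(fp == 0, 1.0, 0.0))
        dsc = np.where(~both_empty, 2 * tp / np.maximum(2 * tp + fp + fn, 1), 1.0)
        jac = np.where(~both_empty, tp / np.maximum(tp + fp + fn, 1), 1.0)
    return prec, rec, dsc, jac, both_empty


def report_from_counts(tp: np.ndarray, fp: np.ndarray, fn: np.ndarray,
                       include_background_weighted: bool = True) -> MetricsReport:
    """Build a report from per-class count arrays (index 0 = background)."""
    prec, rec, dsc, jac, both_empty = _metrics_from(tp, fp, fn)
    support = tp + fn

    s = slice(1, None)  # structures only
    macro = {"precision": float(prec[s].mean()), "recall": float(rec[s].mean()),
             "dice": float(dsc[s].mean()), "iou": float(jac[s].mean())}

    wsel = slice(0, None) if include_background_weighted else s
    w = support[wsel].astype(np.float64)
    if w.sum() == 0:
        w = np.ones_like(w)
    weighted = {k: float(np.average(v[wsel], weights=w))
                for k, v in (("precision", prec), ("recall", rec),
                             ("dice", dsc), ("iou", jac))}

    return MetricsReport(class_ids=np.arange(1, len(tp)),
                         precision=prec[s], recall=rec[s], dice=dsc[s], iou=jac[s],
                         support=support[s].astype(np.int64), both_empty=both_empty[s],
                         macro_average=macro, weighted_average=weighted)


def report(pred, truth, n_classes: int | None = None,
           include_background_weighted: bool = True) -> MetricsReport:
    """Evaluate a predicted label volume against ground truth.

    Metrics are computed for structure IDs 1..S; the macro average is the
    unweighted mean over structures, the weighted average is weighted by
    ground-truth support (background included by default).
    """
    p, t = _as_array(pred), _as_array(truth)
    if n_classes is None:
        n_classes = int(max(p.max(initial=0), t.max(initial=0))) + 1
    tp, fp, fn = confusion_all(p, t, n_classes)
    return report_from_counts(tp, fp, fn,
                              include_background_weighted=include_background_weighted)
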