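"""Segmentation overlap metrics, classification metrics and report assembly.

IoU (Jaccard) and DSC (Dice) are computed from per-class pixel confusion
counts:

    IoU = TP / (TP + FP + FN)        DSC = 2*TP / (2*TP + FP + FN)

and are related by DSC = 2*IoU / (1 + IoU).  Dataset-level numbers are
macro-averaged: the metric is computed per image, then averaged over images
(this pooling convention is fixed and documented so numbers reproduce).
The background class is included in the mean IoU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .vcdr import (
    MissingDiscError,
    classify_vcdr,
    compute_vcdr,
    mean_vcdr_error,
    refit_mask_ellipses,
)

N_CLASSES = 3


@dataclass(frozen=True)
class PixelConfusion:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassificationMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float


@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    map50: float
    map75: float
    map50_95: float


@dataclass
class EvalReport:
    """Aggregate report over a segmentation/classification evaluation set."""

    iou_background: float
    iou_od: float
    iou_oc: float
    dsc_od: float
    dsc_oc: float
    mean_iou: float
    mean_vcdr_error: float
    classification: ClassificationMetrics
    n_images: int
    n_degenerate: int
    detection: DetectionMetrics | None = None
    per_image: list[dict] = field(default_factory=list)


def pixel_confusion(pred_mask: np.ndarray, true_mask: np.ndarray,
                    class_label: int) -> PixelConfusion:
    """Per-class TP/FP/FN/TN pixel counts between two equal-shape masks."""
    pred_mask = np.asarray(pred_mask)
    true_mask = np.asarray(true_mask)
    if pred_mask.shape != true_mask.shape:
        raise ValueError(
            f"shape mismatch: {pred_mask.shape} vs {true_mask.shape}")
    p = pred_mask == class_label
    t = true_mask == class_label
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return PixelConfusion(tp, fp, fn, tn)


def iou_score(conf: PixelConfusion) -> float:
    union = conf.tp + conf.fp + conf.fn
    if union == 0:
        raise ValueError("IoU undefined: empty union (class absent in both masks)")
    return conf.tp / union


def dsc_score(conf: PixelConfusion) -> float:
    denom = 2 * conf.tp + conf.fp + conf.fn
    if denom == 0:
        raise ValueError("DSC undefined: class absent in both masks")
    return 2 * conf.tp / denom


def classification_report(pred_labels: list[str], true_labels: list[str],
                          positive: str = "glaucoma") -> ClassificationMetrics:
    """Accuracy / precision / recall / F1 for binary labels.

    Zero-division cases (e.g. no positive predictions) are reported as NaN,
    never silently as 0.
    """
    if not pred_labels or len(pred_labels) != len(true_labels):
        raise ValueError("label lists must be non-empty and equal length")
    tp = sum(1 for p, t in zip(pred_labels, true_labels)
             if p == positive and t == positive)
    fp = sum(1 for p, t in zip(pred_labels, true_labels)
             if p == positive and t != positive)
    fn = sum(1 for p, t in zip(pred_labels, true_labels)
             if p != positive and t == positive)
    tn = len(pred_labels) - tp - fp - fn
    accuracy = (tp + tn) / len(pred_labels)
    precision = tp / (tp + fp) if tp + fp else math.nan
    recall = tp / (tp + fn) if tp + fn else math.nan
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        f1 = math.nan
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return ClassificationMetrics(accuracy, precision, recall, f1)


def _per_image_class_metrics(pred: np.ndarray, true: np.ndarray):
    ious, dscs = {}, {}
    for c in range(N_CLASSES):
        conf = pixel_confusion(pred, true, c)
        try:
            ious[c] = iou_score(conf)
            dscs[c] = dsc_score(conf)
        except ValueError:  # class absent in both → excluded from the average
            ious[c] = math.nan
            dscs[c] = math.nan
    return ious, dscs


def evaluate_segmentation_set(
    pred_masks: list[np.ndarray],
    true_masks: list[np.ndarray],
    true_vcdrs: list[float],
    refit: bool = True,
    vcdr_threshold: float = 0.5,
    names: list[str] | None = None,
) -> EvalReport:
    """Evaluate predicted masks against ground truth over a dataset.

    Per-class IoU/DSC are macro-averaged over images.  The vCDR pipeline
    (optional ellipse refit, then row-extent vCDR) runs per image; images
    whose prediction has no disc are excluded from the vCDR error but
    counted as degenerate and classified as predicted-normal.
    """
    if not (len(pred_masks) == len(true_masks) == len(true_vcdrs)) or not pred_masks:
        raise ValueError("pred/true/vcdr collections must be aligned and non-empty")
    names = names or [f"image_{i:04d}" for i in range(len(pred_masks))]

    per_class_iou = {c: [] for c in range(N_CLASSES)}
    per_class_dsc = {c: [] for c in range(N_CLASSES)}
    vcdr_pairs: list[tuple[float, float]] = []
    pred_labels, true_labels = [], []
    per_image = []
    n_degenerate = 0

    for name, pred, true, tv in zip(names, pred_masks, true_masks, true_vcdrs):
        ious, dscs = _per_image_class_metrics(pred, true)
        for c in range(N_CLASSES):
            if not math.isnan(ious[c]):
                per_class_iou[c].append(ious[c])
                per_class_dsc[c].append(dscs[c])
        row = {"filename": name, "true_vcdr": tv,
               "iou_od": ious[1], "iou_oc": ious[2]}
        eval_mask = refit_mask_ellipses(pred).mask if refit else pred
        try:
            res = compute_vcdr(eval_mask, threshold=vcdr_threshold)
            vcdr_pairs.append((res.vcdr, tv))
            pred_label = res.label
            row.update(vcdr_pred=res.vcdr, degenerate=res.degenerate)
        except MissingDiscError:
            n_degenerate += 1
            pred_label = "normal"  # no disc found → screen as normal
            row.update(vcdr_pred=math.nan, degenerate=True)
        pred_labels.append(pred_label)
        true_labels.append(classify_vcdr(tv, vcdr_threshold))
        row["pred_label"] = pred_label
        per_image.append(row)

    def _macro(values: list[float]) -> float:
        return float(np.mean(values)) if values else math.nan

    iou_bg = _macro(per_class_iou[0])
    iou_od = _macro(per_class_iou[1])
    iou_oc = _macro(per_class_iou[2])
    mean_iou = float(np.nanmean([iou_bg, iou_od, iou_oc]))
    return EvalReport(
        iou_background=iou_bg,
        iou_od=iou_od,
        iou_oc=iou_oc,
        dsc_od=_macro(per_class_dsc[1]),
        dsc_oc=_macro(per_class_dsc[2]),
        mean_iou=mean_iou,
        mean_vcdr_error=mean_vcdr_error(vcdr_pairs) if vcdr_pairs else math.nan,
        classification=classification_report(pred_labels, true_labels),
        n_images=len(pred_masks),
        n_degenerate=n_degenerate,
        per_image=per_image,
    )
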