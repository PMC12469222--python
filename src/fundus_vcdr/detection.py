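"""Optic-disc localization, NMS filtering, square ROI cropping and mAP.

Boxes are axis-aligned, half-open pixel intervals [x_min, x_max) x
[y_min, y_max), 0-based with the origin at the top-left corner (x grows
rightward, y downward).  The half-open convention makes areas and
intersections integer-exact on the pixel lattice.

The built-in detector :func:`detect_od_bright` is a brightness-based
stand-in for a learned object detector: the optic disc is the bright
central structure of a fundus image, so smoothing, high-percentile
thresholding and connected components recover it directly on images whose
disc/background contrast follows that pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters


@dataclass(frozen=True)
class BBox:
    """Half-open axis-aligned pixel box with a confidence score."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float
    confidence: float = 1.0
    class_id: int = 0

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x_min + self.x_max) / 2, (self.y_min + self.y_max) / 2)


@dataclass(frozen=True)
class CropRecord:
    source_box: BBox
    margin: int
    side: int
    window: BBox


def iou_boxes(a: BBox, b: BBox) -> float:
    """Intersection over union of two boxes; symmetric, in [0, 1]."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def nms_filter(boxes: list[BBox], conf_thresh: float = 0.5,
               iou_thresh: float = 0.3) -> list[BBox]:
    """Confidence filtering followed by greedy non-maximum suppression.

    Boxes below ``conf_thresh`` are dropped.  The remaining boxes are
    processed in order of descending confidence (ties broken by x_min then
    y_min ascending); a box overlapping an already-kept box with
    IoU > ``iou_thresh`` is suppressed.  The defaults (0.5, 0.3) keep a
    single box per optic disc even under mild duplicate overlap.
    """
    candidates = sorted(
        (b for b in boxes if b.confidence >= conf_thresh),
        key=lambda b: (-b.confidence, b.x_min, b.y_min),
    )
    kept: list[BBox] = []
    for box in candidates:
        if all(iou_boxes(box, k) <= iou_thresh for k in kept):
            kept.append(box)
    return kept


def detect_od_bright(
    image: np.ndarray,
    smooth_sigma: float = 5.0,
    percentile: float = 95.0,
    min_area: int = 50,
    conf_thresh: float = 0.5,
    iou_thresh: float = 0.3,
) -> list[BBox]:
    """Locate bright disc-like regions and return NMS-filtered boxes.

    Pipeline: grayscale → Gaussian smoothing → threshold at a high
    intensity percentile → 8-connected components → one box per component.
    The pseudo-confidence of a component is its mean smoothed brightness
    normalized to [0, 1], so a genuinely bright disc scores well above the
    0.5 confidence cut while dim speckle falls below it.
    Returns an empty list when nothing exceeds the threshold.
    """
    image = np.asarray(image)
    if image.ndim == 3:
        gray = image.astype(float).mean(axis=2)
    else:
        gray = image.astype(float)
    smoothed = filters.gaussian(gray, sigma=smooth_sigma, preserve_range=True)
    thresh = np.percentile(smoothed, percentile)
    binary = smoothed > thresh
    if not binary.any():
        return []
    labeled, n = ndimage.label(binary, structure=np.ones((3, 3), dtype=int))
    boxes: list[BBox] = []
    for sl, lab in zip(ndimage.find_objects(labeled), range(1, n + 1)):
        if sl is None:
            continue
        comp = labeled[sl] == lab
        if comp.sum() < min_area:
            continue
        conf = float(smoothed[sl][comp].mean() / 255.0)
        ys, xs = sl
        boxes.append(BBox(float(xs.start), float(ys.start),
                          float(xs.stop), float(ys.stop),
                          confidence=min(conf, 1.0)))
    return nms_filter(boxes, conf_thresh=conf_thresh, iou_thresh=iou_thresh)


def box_from_mask(mask: np.ndarray, labels: tuple[int, ...] = (1, 2)) -> BBox:
    """Tight bounding box of the given mask labels (ground-truth box)."""
    region = np.isin(np.asarray(mask), labels)
    ys, xs = np.nonzero(region)
    if ys.size == 0:
        raise ValueError("mask contains none of the requested labels")
    return BBox(float(xs.min()), float(ys.min()),
                float(xs.max() + 1), float(ys.max() + 1))


def crop_square_roi(
    image: np.ndarray,
    mask: np.ndarray | None,
    box: BBox,
    margin: int = 70,
) -> tuple[np.ndarray, np.ndarray | None, CropRecord]:
    """Crop a square window around a detected box, margin added on all sides.

    The box is expanded by ``margin`` pixels in every direction; the square
    side is the larger of the expanded width and height; the window is
    centered on the expanded box and, if it would leave the frame, shifted
    (never shrunk) back inside.  A square crop keeps the disc and cup
    aspect ratio intact under later resizing, which is what makes the vCDR
    invariant to that resize.  The identical window is applied to the mask.

    Raises
    ------
    ValueError
        If the frame is smaller than the required square.
    """
    h, w = np.asarray(image).shape[:2]
    ex0, ey0 = box.x_min - margin, box.y_min - margin
    ex1, ey1 = box.x_max + margin, box.y_max + margin
    # snap to a 1e-3 pixel grid so boxes that round-tripped through a
    # normalized annotation format (6-decimal quantization) crop identically
    side = int(np.ceil(round(max(ex1 - ex0, ey1 - ey0), 3)))
    if side > w or side > h:
        raise ValueError(
            f"square crop of side {side} does not fit a {w}x{h} frame")
    cx, cy = (ex0 + ex1) / 2, (ey0 + ey1) / 2
    x0 = int(round(round(cx - side / 2, 3)))
    y0 = int(round(round(cy - side / 2, 3)))
    x0 = min(max(x0, 0), w - side)
    y0 = min(max(y0, 0), h - side)
    window = BBox(float(x0), float(y0), float(x0 + side), float(y0 + side))
    img_crop = np.asarray(image)[y0 : y0 + side, x0 : x0 + side]
    mask_crop = None
    if mask is not None:
        mask_crop = np.asarray(mask)[y0 : y0 + side, x0 : x0 + side]
    record = CropRecord(source_box=box, margin=margin, side=side, window=window)
    return img_crop, mask_crop, record


def match_detections(
    preds: list[BBox], gts: list[BBox], iou_thresh: float = 0.5
) -> list[tuple[BBox, BBox | None]]:
    """Greedy one-to-one matching of predictions to ground truth.

    Predictions are visited in descending confidence; each claims the
    unmatched ground-truth box of highest IoU provided that IoU is strictly
    above ``iou_thresh``, otherwise it is a false positive (matched to
    None).  Ground-truth boxes left unmatched are false negatives.
    """
    order = sorted(range(len(preds)),
                   key=lambda i: (-preds[i].confidence,
                                  preds[i].x_min, preds[i].y_min))
    taken = [False] * len(gts)
    matches: list[tuple[BBox, BBox | None]] = [None] * len(preds)  # type: ignore
    for i in order:
        best_j, best_iou = -1, iou_thresh
        for j, gt in enumerate(gts):
            if taken[j]:
                continue
            iou = iou_boxes(preds[i], gt)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0:
            taken[best_j] = True
            matches[i] = (preds[i], gts[best_j])
        else:
            matches[i] = (preds[i], None)
    return matches


def detection_counts(preds: list[BBox], gts: list[BBox],
                     iou_thresh: float = 0.5) -> tuple[int, int, int]:
    """(TP, FP, FN) under greedy matching at the given IoU threshold."""
    matches = match_detections(preds, gts, iou_thresh)
    tp = sum(1 for _, gt in matches if gt is not None)
    return tp, len(preds) - tp, len(gts) - tp


def average_precision(preds: list[BBox], gts: list[BBox],
                      iou_thresh: float = 0.5) -> float:
    """Average precision by 101-point interpolation of the PR curve.

    Predictions are ranked by confidence; at each rank the cumulative
    precision/recall is computed, precision is made monotone from the
    right, and AP is the mean of the interpolated precision at recall
    levels {0, 0.01, ..., 1}.
    """
    if not gts:
        raise ValueError("average precision undefined with zero ground-truth boxes")
    if not preds:
        return 0.0
    matches = match_detections(preds, gts, iou_thresh)
    order = sorted(range(len(preds)), key=lambda i: -preds[i].confidence)
    tp_flags = np.array([matches[i][1] is not None for i in order], dtype=float)
    cum_tp = np.cumsum(tp_flags)
    precision = cum_tp / np.arange(1, len(preds) + 1)
    recall = cum_tp / len(gts)
    # monotone envelope from the right
    precision = np.maximum.accumulate(precision[::-1])[::-1]
    recall_grid = np.linspace(0.0, 1.0, 101)
    interp = np.zeros_like(recall_grid)
    for k, r in enumerate(recall_grid):
        mask = recall >= r - 1e-12
        interp[k] = precision[mask].max() if mask.any() else 0.0
    return float(interp.mean())


def mean_ap(preds: list[BBox], gts: list[BBox],
            thresholds: np.ndarray | None = None) -> float:
    """mAP over IoU thresholds; defaults to the 0.50:0.05:0.95 ladder.

    With a single object class the per-threshold mAP equals the AP.
    """
    if thresholds is None:
        thresholds = np.arange(0.50, 0.951, 0.05)
    return float(np.mean([average_precision(preds, gts, t) for t in thresholds]))
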