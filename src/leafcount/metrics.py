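"""Evaluation metrics for leaf segmentation, insect detection and counting.

Segmentation quality is scored per pixel (pixel accuracy, IoU, Dice/F1).
Detection quality uses the standard confidence-ordered greedy matching at an
IoU threshold, per-class precision/recall, and average precision as the area
under the all-point interpolated precision-recall curve; mAP is the plain
mean of per-class APs.  Counting quality is the root-mean-square error
between predicted and true per-image counts, reported overall (classes
summed per image) and per class.  Boxes are also binned into the COCO
absolute-area scale classes (small < 32x32, medium up to 96x96, large
above), which is how the survey targets — median adult 24x25 px, median
nymph 19x19 px — are characterised as a small-object problem.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import Detection


class ZeroGroundTruthError(ValueError):
    """Average precision is undefined for a class with no ground truth."""


# ---------------------------------------------------------------- segmentation


def seg_metrics(pred: np.ndarray, gt: np.ndarray) -> tuple[float, float, float]:
    """Pixel accuracy, IoU and F1 (Dice) of a predicted binary mask.

    PA = (TP + TN) / all pixels; IoU = |A∩B| / |A∪B|; F1 = 2|A∩B| / (|A|+|B|)
    with A = predicted foreground, B = true foreground.  Convention: if both
    masks are empty, IoU = F1 = 1 (perfect agreement on "nothing").
    """
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    inter = int(np.count_nonzero(pred & gt))
    a = int(np.count_nonzero(pred))
    b = int(np.count_nonzero(gt))
    union = a + b - inter
    pa = float(np.count_nonzero(pred == gt)) / pred.size
    iou = 1.0 if union == 0 else inter / union
    f1 = 1.0 if a + b == 0 else 2.0 * inter / (a + b)
    return pa, iou, f1


# ------------------------------------------------------------------- matching


@dataclass
class MatchResult:
    """Per-class TP/FP/FN tallies plus per-detection flags for PR curves."""

    tp: dict[str, int] = field(default_factory=dict)
    fp: dict[str, int] = field(default_factory=dict)
    fn: dict[str, int] = field(default_factory=dict)
    # (confidence, is_tp) per detection, grouped by class
    flags: dict[str, list[tuple[float, bool]]] = field(default_factory=dict)
    n_gt: dict[str, int] = field(default_factory=dict)

    def precision(self, label: str) -> float:
        tp, fp = self.tp.get(label, 0), self.fp.get(label, 0)
        return tp / (tp + fp) if tp + fp else 1.0

    def recall(self, label: str) -> float:
        tp, fn = self.tp.get(label, 0), self.fn.get(label, 0)
        return tp / (tp + fn) if tp + fn else 1.0


def match_detections(
    dets: list[Detection], gts: list[Detection], iou_threshold: float = 0.5
) -> MatchResult:
    """Greedy confidence-ordered matching of detections to ground truth.

    Detections are visited in order of decreasing confidence (ties by input
    index).  Each is matched to the not-yet-matched same-class ground truth
    with the highest IoU, provided that IoU reaches the threshold; matched
    detections are true positives, the rest false positives, and unmatched
    ground truths false negatives.
    """
    if not (0.0 <= iou_threshold <= 1.0):
        raise ValueError("iou_threshold must lie in [0, 1]")
    res = MatchResult()
    labels = {d.label for d in dets} | {g.label for g in gts}
    for lab in labels:
        res.tp[lab] = res.fp[lab] = res.fn[lab] = 0
        res.flags[lab] = []
        res.n_gt[lab] = sum(1 for g in gts if g.label == lab)
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    matched_gt: set[int] = set()
    for i in order:
        det = dets[i]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(gts):
            if j in matched_gt or g.label != det.label:
                continue
            iou = det.box.iou(g.box)
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_threshold:
            matched_gt.add(best_j)
            res.tp[det.label] += 1
            res.flags[det.label].append((det.confidence, True))
        else:
            res.fp[det.label] += 1
            res.flags[det.label].append((det.confidence, False))
    for j, g in enumerate(gts):
        if j not in matched_gt:
            res.fn[g.label] += 1
    return res


def average_precision(matches: list[MatchResult], label: str) -> float:
    """AP of one class across images: area under the interpolated PR curve.

    All per-image detection flags are pooled and re-sorted by confidence;
    precision at recall r is replaced by the maximum precision at any
    recall >= r (all-point interpolation) before integrating over recall.
    """
    n_gt = sum(m.n_gt.get(label, 0) for m in matches)
    if n_gt == 0:
        raise ZeroGroundTruthError(f"no ground-truth instances of class {label!r}")
    flags = [fl for m in matches for fl in m.flags.get(label, [])]
    if not flags:
        return 0.0
    flags.sort(key=lambda t: -t[0])
    tp_cum = np.cumsum([1.0 if is_tp else 0.0 for _, is_tp in flags])
    fp_cum = np.cumsum([0.0 if is_tp else 1.0 for _, is_tp in flags])
    recall = tp_cum / n_gt
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    # running maximum from the right = interpolated precision
    p_interp = np.maximum.accumulate(precision[::-1])[::-1]
    r_prev = 0.0
    ap = 0.0
    for r, p in zip(recall, p_interp):
        if r > r_prev:
            ap += (r - r_prev) * p
            r_prev = r
    return float(ap)


def mean_average_precision(matches: list[MatchResult], labels: list[str]) -> float:
    """Plain mean of per-class AP over ``labels`` (n = len(labels))."""
    return float(np.mean([average_precision(matches, lab) for lab in labels]))


# ------------------------------------------------------------------- counting


@dataclass
class CountReport:
    """Predicted (and optionally true) per-class counts for one image."""

    predicted: dict[str, int]
    truth: dict[str, int] | None = None


def count_rmse(reports: list[CountReport]) -> dict[str, float]:
    """RMSE between predicted and true counts: sqrt(mean((pred - gt)^2)).

    Returns ``{"overall": ..., <class>: ...}`` where "overall" uses each
    image's total count summed over classes and the per-class entries use
    that class's count alone.
    """
    if not reports:
        raise ValueError("count_rmse needs at least one image")
    if any(r.truth is None for r in reports):
        raise ValueError("count_rmse needs ground-truth counts for every image")
    labels = sorted({lab for r in reports for lab in set(r.predicted) | set(r.truth)})
    out: dict[str, float] = {}
    total_sq = [
        (sum(r.predicted.values()) - sum(r.truth.values())) ** 2 for r in reports
    ]
    out["overall"] = float(np.sqrt(np.mean(total_sq)))
    for lab in labels:
        sq = [(r.predicted.get(lab, 0) - r.truth.get(lab, 0)) ** 2 for r in reports]
        out[lab] = float(np.sqrt(np.mean(sq)))
    return out


# ------------------------------------------------------------- scale classes


def classify_scale(width: float, height: float) -> str:
    """COCO absolute-area scale class of a box.

    small: area < 32*32; medium: 32*32 <= area <= 96*96; large: area > 96*96.
    The medium band is closed at both ends.
    """
    if width <= 0 or height <= 0:
        raise ValueError("box dimensions must be positive")
    area = width * height
    if area < 32 * 32:
        return "small"
    if area <= 96 * 96:
        return "medium"
    return "large"


# ------------------------------------------------------------ dataset stats


def dataset_stats(annotations: list[list[Detection]]) -> dict:
    """Descriptive statistics of an annotated image set.

    ``annotations`` holds one ground-truth list per image.  Returns, per
    class: median box width/height, scale-class fractions, and per-image
    count mean / SD (population) / min / max.
    """
    if not annotations:
        raise ValueError("need at least one annotated image")
    labels = sorted({d.label for anns in annotations for d in anns})
    stats: dict = {"n_images": len(annotations), "classes": {}}
    for lab in labels:
        widths = [d.box.width for anns in annotations for d in anns if d.label == lab]
        heights = [d.box.height for anns in annotations for d in anns if d.label == lab]
        scales = [
            classify_scale(w, h) for w, h in zip(widths, heights)
        ]
        counts = np.array([sum(1 for d in anns if d.label == lab) for anns in annotations])
        n_boxes = len(widths)
        stats["classes"][lab] = {
            "n_boxes": n_boxes,
            "median_width": float(np.median(widths)) if widths else None,
            "median_height": float(np.median(heights)) if heights else None,
            "scale_fractions": {
                s: scales.count(s) / n_boxes for s in ("small", "medium", "large")
            }
            if n_boxes
            else {},
            "count_mean": float(counts.mean()),
            "count_sd": float(counts.std()),
            "count_min": int(counts.min()),
            "count_max": int(counts.max()),
        }
    return stats


# ----------------------------------------------------------------- reporting


@dataclass
class MetricsReport:
    """Aggregate detection/segmentation/counting report for a dataset."""

    per_class: dict[str, dict[str, float]]
    map50: float
    seg: dict[str, float] | None = None
    rmse: dict[str, float] | None = None

    def as_dict(self) -> dict:
        out: dict = {"per_class": self.per_class, "mAP50": self.map50}
        if self.seg is not None:
            out["segmentation"] = self.seg
        if self.rmse is not None:
            out["count_rmse"] = self.rmse
        return out


def detection_report(
    matches: list[MatchResult],
    labels: list[str],
    rmse: dict[str, float] | None = None,
    seg: dict[str, float] | None = None,
) -> MetricsReport:
    per_class = {}
    for lab in labels:
        tp = sum(m.tp.get(lab, 0) for m in matches)
        fp = sum(m.fp.get(lab, 0) for m in matches)
        fn = sum(m.fn.get(lab, 0) for m in matches)
        per_class[lab] = {
            "precision": tp / (tp + fp) if tp + fp else 1.0,
            "recall": tp / (tp + fn) if tp + fn else 1.0,
            "ap": average_precision(matches, lab),
        }
    map50 = float(np.mean([v["ap"] for v in per_class.values()]))
    return MetricsReport(per_class=per_class, map50=map50, seg=seg, rmse=rmse)
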