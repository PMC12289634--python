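"""Per-class segmentation metrics and inference timing.

Dice (DSC = 2|T∩P| / (|T|+|P|)) is the primary metric; IoU, F1, precision
and recall are computed from the same per-class confusion counts. Metrics
are macro-averaged over images by default (the per-image values are averaged,
rather than pooling pixel counts across the dataset). Empty-class convention:
a class absent from both prediction and target scores 1, absent from only
one scores 0 — needed because severely obstructed scenes can have a
near-empty airway class.
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from .model import SegmentationModel, predict
from .synthetic import Sample

CLASS_NAMES = {1: "trachea", 2: "supraglottis"}
METRIC_NAMES = ("dice", "iou", "f1", "precision", "recall")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass
class MetricsReport:
    """Per-class metric table plus how it was aggregated."""

    per_class: dict[str, dict[str, float]]      # class name -> metric -> value
    aggregation: str = "macro_over_images"
    n_images: int = 0

    def mean_dice(self) -> float:
        return float(np.mean([m["dice"] for m in self.per_class.values()]))


@dataclass
class TimingReport:
    duration_ms: float          # mean wall-clock per single-image forward
    fps: float                  # 1000 / duration_ms
    n_warmup: int
    n_timed: int


def _check_shapes(pred, target):
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    return pred, target


def dice(pred: np.ndarray, target: np.ndarray, cls: int) -> float:
    """Dice similarity of the binary masks ``pred == cls`` / ``target == cls``."""
    pred, target = _check_shapes(pred, target)
    p = pred == cls
    t = target == cls
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(p, t).sum()) / denom


def confusion(pred: np.ndarray, target: np.ndarray, cls: int) -> ConfusionCounts:
    pred, target = _check_shapes(pred, target)
    p = pred == cls
    t = target == cls
    tp = int(np.logical_and(p, t).sum())
    fp = int(np.logical_and(p, ~t).sum())
    fn = int(np.logical_and(~p, t).sum())
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _safe_ratio(num: int, denom: int, class_absent_everywhere: bool) -> float:
    if denom == 0:
        return 1.0 if class_absent_everywhere else 0.0
    return num / denom


def metrics_from_counts(counts: ConfusionCounts) -> dict[str, float]:
    """IoU, precision, recall, F1 (and Dice) from one class's confusion counts."""
    absent = counts.tp + counts.fp + counts.fn == 0
    iou = _safe_ratio(counts.tp, counts.tp + counts.fp + counts.fn, absent)
    precision = _safe_ratio(counts.tp, counts.tp + counts.fp, absent)
    recall = _safe_ratio(counts.tp, counts.tp + counts.fn, absent)
    if precision + recall == 0:
        f1 = 1.0 if absent else 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    dsc = _safe_ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn, absent)
    return {"dice": dsc, "iou": iou, "f1": f1, "precision": precision, "recall": recall}


def evaluate_masks(preds: list[np.ndarray], targets: list[np.ndarray],
                   classes=(1, 2), aggregation: str = "macro_over_images") -> MetricsReport:
    """Metric report for aligned lists of predicted and ground-truth masks."""
    if not preds:
        raise ValueError("empty sample list")
    if len(preds) != len(targets):
        raise ValueError("pred/target counts differ")
    per_class: dict[str, dict[str, float]] = {}
    for cls in classes:
        name = CLASS_NAMES.get(cls, f"class_{cls}")
        if aggregation == "macro_over_images":
            rows = [metrics_from_counts(confusion(p, t, cls))
                    for p, t in zip(preds, targets)]
            per_class[name] = {m: float(np.mean([r[m] for r in rows]))
                               for m in METRIC_NAMES}
        elif aggregation == "pixel_pooled":
            totals = np.sum([[c.tp, c.fp, c.fn, c.tn] for c in
                             (confusion(p, t, cls) for p, t in zip(preds, targets))], axis=0)
            per_class[name] = metrics_from_counts(ConfusionCounts(*map(int, totals)))
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
    return MetricsReport(per_class=per_class, aggregation=aggregation,
                         n_images=len(preds))


def evaluate(model: SegmentationModel, samples: list[Sample],
             postprocess_on: bool = False, post_config=None,
             aggregation: str = "macro_over_images") -> MetricsReport:
    """Run the model over samples and score the (optionally refined) masks."""
    if not samples:
        raise ValueError("empty sample list")
    preds = list(predict([s.image for s in samples], model))
    if postprocess_on:
        from .postprocess import PostConfig, postprocess
        cfg = post_config or PostConfig.for_image_size(samples[0].mask.shape)
        preds = [postprocess(p, cfg) for p in preds]
    return evaluate_masks(preds, [s.mask for s in samples], aggregation=aggregation)


def time_inference(model: SegmentationModel, images: list[np.ndarray],
                   n_warmup: int = 5, n_timed: int = 10) -> TimingReport:
    """Mean single-image forward-pass wall-clock time and the implied FPS."""
    if n_timed < 1:
        raise ValueError("n_timed must be >= 1")
    seq = [np.asarray(images[i % len(images)]) for i in range(n_warmup + n_timed)]
    for im in seq[:n_warmup]:
        predict([im], model)
    t0 = time.perf_counter()
    for im in seq[n_warmup:]:
        predict([im], model)
    duration_ms = (time.perf_counter() - t0) * 1000.0 / n_timed
    return TimingReport(duration_ms=duration_ms, fps=1000.0 / duration_ms,
                        n_warmup=n_warmup, n_timed=n_timed)
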