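"""Segmentation and detection metrics.

Segmentation quality is measured by the Dice coefficient
``2|A ∩ B| / (|A| + |B|)`` per class (axon and myelin binarizations) and by
pixel-wise accuracy over all three classes.  Detection quality is measured
at the object level: 8-connected components of the axon class are matched
by assigning each predicted object's centroid to the ground-truth object
containing it, giving TP/FP/FN counts and from them the sensitivity
``TPR = TP/(TP+FN)`` and precision ``PPV = TP/(TP+FP)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

from .imagery import SegmentationMask

__all__ = ["DetectionCounts", "MetricReport", "dice", "pixel_accuracy",
           "detect_axons", "evaluate"]

AXON_CLASS = 2
MYELIN_CLASS = 1


@dataclass
class DetectionCounts:
    """Object-level confusion counts for axon detection."""

    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        """TPR = TP / (TP + FN); 0 when there are no ground-truth objects."""
        denom = self.tp + self.fn
        return self.tp / denom if denom else 0.0

    @property
    def precision(self) -> float:
        """PPV = TP / (TP + FP); 0 when there are no predicted objects."""
        denom = self.tp + self.fp
        return self.tp / denom if denom else 0.0

    @property
    def undefined_sensitivity(self) -> bool:
        return self.tp + self.fn == 0

    @property
    def undefined_precision(self) -> bool:
        return self.tp + self.fp == 0


@dataclass
class MetricReport:
    """The five evaluation metrics, all dimensionless in [0, 1]."""

    axon_dice: float
    myelin_dice: float
    pixel_accuracy: float
    sensitivity: float
    precision: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"axon_dice": self.axon_dice, "myelin_dice": self.myelin_dice,
                "pixel_accuracy": self.pixel_accuracy,
                "sensitivity": self.sensitivity, "precision": self.precision,
                "flags": self.flags}


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient between two binary masks; 1 if both are empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def _classes(mask) -> np.ndarray:
    return mask.classes if isinstance(mask, SegmentationMask) else np.asarray(mask)


def pixel_accuracy(pred, truth) -> float:
    """Fraction of pixels whose predicted class matches the ground truth."""
    p, t = _classes(pred), _classes(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    return float(np.mean(p == t))


def detect_axons(pred, truth) -> DetectionCounts:
    """Match predicted axon objects to ground-truth objects by centroid.

    Each predicted component's centroid (rounded to the nearest pixel) is
    looked up in the labelled ground-truth axon mask.  A ground-truth object
    containing at least one predicted centroid is a TP; one containing none
    is an FN.  Predicted objects whose centroid falls in no ground-truth
    object are FPs, as are surplus predicted centroids beyond the first
    within a single ground-truth object (over-segmentation).
    """
    p, t = _classes(pred), _classes(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    truth_lab, n_truth = label(t == AXON_CLASS, connectivity=2, return_num=True)
    pred_lab, n_pred = label(p == AXON_CLASS, connectivity=2, return_num=True)
    hits = np.zeros(n_truth + 1, dtype=int)  # predicted centroids per truth object
    fp = 0
    for region in regionprops(pred_lab):
        r, c = (int(round(x)) for x in region.centroid)
        r = min(max(r, 0), t.shape[0] - 1)
        c = min(max(c, 0), t.shape[1] - 1)
        owner = truth_lab[r, c]
        if owner == 0:
            fp += 1
        else:
            hits[owner] += 1
    tp = int(np.count_nonzero(hits[1:]))
    fp += int(hits[1:].sum() - tp)  # surplus centroids in one object
    fn = n_truth - tp
    return DetectionCounts(tp=tp, fp=fp, fn=fn)


def evaluate(pred, truth) -> MetricReport:
    """Assemble the five metrics for a predicted/ground-truth mask pair."""
    p, t = _classes(pred), _classes(truth)
    counts = detect_axons(p, t)
    flags = []
    if counts.undefined_sensitivity:
        flags.append("sensitivity undefined (no ground-truth axon objects); reported as 0")
    if counts.undefined_precision:
        flags.append("precision undefined (no predicted axon objects); reported as 0")
    return MetricReport(
        axon_dice=dice(p == AXON_CLASS, t == AXON_CLASS),
        myelin_dice=dice(p == MYELIN_CLASS, t == MYELIN_CLASS),
        pixel_accuracy=pixel_accuracy(p, t),
        sensitivity=counts.sensitivity,
        precision=counts.precision,
        flags=flags,
    )
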