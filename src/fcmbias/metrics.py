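"""Correction and segmentation quality metrics.

Covers overlap scores (Dice/Jaccard), the coefficient of variation of
within-class intensities (the standard inhomogeneity measure: it drops when
a multiplicative bias is removed), a scale-free Pearson score for bias-field
recovery, the grayscale-consistency shift, and the standard diagnostic rates
computed from a confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import nan
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .correction import CorrectionResult
from .phantom import Phantom


def dice(labels_a: np.ndarray, labels_b: np.ndarray, class_id: int) -> float:
    """Dice overlap ``2|A∩B| / (|A|+|B|)``; 1.0 when both classes are empty."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label arrays must have the same shape")
    ma, mb = a == class_id, b == class_id
    denom = ma.sum() + mb.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float((ma & mb).sum()) / float(denom)


def jaccard(labels_a: np.ndarray, labels_b: np.ndarray, class_id: int) -> float:
    """Jaccard overlap ``|A∩B| / |A∪B|``; 1.0 when both classes are empty."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label arrays must have the same shape")
    ma, mb = a == class_id, b == class_id
    union = (ma | mb).sum()
    if union == 0:
        return 1.0
    return float((ma & mb).sum()) / float(union)


def coefficient_of_variation(image: np.ndarray, labels: np.ndarray,
                             class_id: int) -> float:
    """Population std / mean of the class intensities (scale-invariant)."""
    vals = np.asarray(image, dtype=float)[np.asarray(labels) == class_id]
    if vals.size == 0:
        raise ValueError(f"class {class_id} is empty")
    mean = vals.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero-mean class")
    return float(vals.std() / mean)


def bias_recovery_score(estimated: np.ndarray, truth: np.ndarray,
                        mask: np.ndarray) -> float:
    """Pearson correlation of mean-normalized bias fields over foreground.

    The model identifies the bias only up to a multiplicative constant
    (``I/h`` absorbs it into the centers), so each field is divided by its
    own foreground mean before correlating.
    """
    m = np.asarray(mask, dtype=bool)
    e = np.asarray(estimated, dtype=float)[m]
    t = np.asarray(truth, dtype=float)[m]
    if e.shape != t.shape or e.size < 2:
        raise ValueError("fields must share the grid with >= 2 foreground pixels")
    e = e / e.mean()
    t = t / t.mean()
    if e.std() == 0 or t.std() == 0:
        raise ValueError("bias recovery undefined for a constant field")
    return float(np.corrcoef(e, t)[0, 1])


def grayscale_consistency(before: np.ndarray, after: np.ndarray,
                          mask: np.ndarray) -> float:
    """Relative shift of the foreground mean: ``|mean_after - mean_before| / mean_before``."""
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("foreground is empty")
    mb = float(np.asarray(before, dtype=float)[m].mean())
    if mb <= 0:
        raise ValueError("grayscale consistency undefined for nonpositive before-mean")
    ma = float(np.asarray(after, dtype=float)[m].mean())
    return abs(ma - mb) / mb


def diagnostic_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV, accuracy from confusion counts.

    A metric with a zero denominator is reported as ``nan`` (undefined),
    never as 0.
    """
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a nonnegative integer")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("confusion counts are all zero")

    def ratio(num: int, den: int) -> float:
        return num / den if den > 0 else nan

    return {
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
        "accuracy": (tp + tn) / total,
    }


# ---------------------------------------------------------------------------
# end-to-end report
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    dice_per_class: dict[int, float] = field(default_factory=dict)
    jaccard_per_class: dict[int, float] = field(default_factory=dict)
    cv_before: dict[int, float] = field(default_factory=dict)
    cv_after: dict[int, float] = field(default_factory=dict)
    bias_recovery: float = nan
    grayscale_shift: float = nan
    n_iter: int = 0
    converged: bool = False

    @property
    def mean_dice(self) -> float:
        return float(np.mean(list(self.dice_per_class.values())))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in sorted(self.dice_per_class):
            rows.append({
                "class": c,
                "dice": self.dice_per_class[c],
                "jaccard": self.jaccard_per_class[c],
                "cv_before": self.cv_before[c],
                "cv_after": self.cv_after[c],
            })
        frame = pd.DataFrame(rows)
        frame["bias_recovery"] = self.bias_recovery
        frame["grayscale_shift"] = self.grayscale_shift
        frame["n_iter"] = self.n_iter
        frame["converged"] = self.converged
        return frame

    def save(self, csv_path: str | Path, txt_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(csv_path, index=False)
        if txt_path is not None:
            lines = []
            for key, val in asdict(self).items():
                lines.append(f"{key} = {val}")
            lines.append(f"mean_dice = {self.mean_dice}")
            Path(txt_path).write_text("\n".join(lines) + "\n")


def match_classes(predicted: np.ndarray, truth: np.ndarray,
                  n_classes: int) -> dict[int, int]:
    """Best-overlap assignment predicted-class -> true-class (Hungarian).

    Cluster indices are arbitrary, so overlap-maximal matching is applied
    before any per-class score is computed.
    """
    overlap = np.zeros((n_classes, n_classes))
    for i in range(1, n_classes + 1):
        pi = predicted == i
        for j in range(1, n_classes + 1):
            overlap[i - 1, j - 1] = (pi & (truth == j)).sum()
    rows, cols = linear_sum_assignment(-overlap)
    return {int(r) + 1: int(c) + 1 for r, c in zip(rows, cols)}


def evaluate_run(result: CorrectionResult, phantom: Phantom) -> EvaluationReport:
    """Assemble the full quality report for a run against phantom truth."""
    truth = phantom.true_labels
    if result.labels.shape != truth.shape:
        raise ValueError("result and phantom grids differ")
    d = len(result.centers)
    mapping = match_classes(result.labels, truth, d)
    remapped = np.zeros_like(result.labels)
    for pred_c, true_c in mapping.items():
        remapped[result.labels == pred_c] = true_c

    report = EvaluationReport(n_iter=result.n_iter, converged=result.converged)
    for c in range(1, d + 1):
        report.dice_per_class[c] = dice(remapped, truth, c)
        report.jaccard_per_class[c] = jaccard(remapped, truth, c)
        report.cv_before[c] = coefficient_of_variation(phantom.image, truth, c)
        report.cv_after[c] = coefficient_of_variation(result.corrected, truth, c)
    try:
        report.bias_recovery = bias_recovery_score(result.bias_field,
                                                   phantom.true_bias, result.mask)
    except ValueError:
        report.bias_recovery = nan  # constant field (e.g. bias frozen at 1)
    report.grayscale_shift = grayscale_consistency(result.filtered,
                                                   result.corrected, result.mask)
    return report
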