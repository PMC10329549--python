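"""Evaluation metrics: segmentation error, confusion matrix, screening
diagnostics, and rater agreement.

Segmentation is scored by the misclassification error (ME, fraction of
pixels whose object/background assignment disagrees with ground truth) and
the relative foreground area error (RAE, normalized absolute difference of
foreground areas). Classification is summarized by the 3-class confusion
matrix and, after collapsing to "low bone density" (osteopenia or
osteoporosis) versus normal, by sensitivity, specificity, accuracy and the
likelihood ratios LR+ = sens/(1−spec) and LR− = (1−sens)/spec, with exact
Clopper–Pearson 95% intervals on the proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .roi_io import CLASS_ORDER, ClassLabel, CorticalMask


@dataclass(frozen=True)
class SegmentationErrors:
    me: float
    rae: float


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 counts; rows = actual class, cols = predicted, both in the order
    normal, osteopenia, osteoporosis."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (3, 3) or (c < 0).any():
            raise ValueError("confusion matrix must be 3x3 with non-negative counts")
        object.__setattr__(self, "counts", c)

    @property
    def actual_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def predicted_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class BinaryDiagnostics:
    sensitivity: float
    specificity: float
    accuracy: float
    lr_pos: Optional[float]
    lr_neg: Optional[float]
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    accuracy_ci: tuple[float, float]


def _as_bool(mask: CorticalMask | np.ndarray) -> np.ndarray:
    if isinstance(mask, CorticalMask):
        return mask.pixels
    return np.asarray(mask).astype(bool)


def misclassification_error(gt: CorticalMask | np.ndarray, pred: CorticalMask | np.ndarray) -> float:
    """ME = 1 − (|B∩B| + |F∩F|) / n — the fraction of disagreeing pixels.

    0 for identical masks, 1 for complementary ones; symmetric in its
    arguments.
    """
    g, p = _as_bool(gt), _as_bool(pred)
    if g.shape != p.shape:
        raise ValueError(f"shape mismatch: {g.shape} vs {p.shape}")
    agree = np.count_nonzero(g == p)
    return 1.0 - agree / g.size


def relative_foreground_area_error(
    gt: CorticalMask | np.ndarray, pred: CorticalMask | np.ndarray
) -> float:
    """RAE = (A_g − A_p)/A_g if the prediction undershoots, else
    (A_p − A_g)/A_p; always in [0, 1]."""
    g, p = _as_bool(gt), _as_bool(pred)
    a_g = int(np.count_nonzero(g))
    a_p = int(np.count_nonzero(p))
    if a_g == 0:
        raise ValueError("ground truth has no foreground; RAE undefined")
    if a_p < a_g:
        return (a_g - a_p) / a_g
    return (a_p - a_g) / a_p


def segmentation_errors(gt: CorticalMask, pred: CorticalMask) -> SegmentationErrors:
    return SegmentationErrors(
        me=misclassification_error(gt, pred),
        rae=relative_foreground_area_error(gt, pred),
    )


def confusion_matrix(
    actual: Sequence[ClassLabel | str], predicted: Sequence[ClassLabel | str]
) -> ConfusionMatrix3:
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted label lists differ in length")
    if len(actual) == 0:
        raise ValueError("empty label lists")
    index = {label: i for i, label in enumerate(CLASS_ORDER)}
    counts = np.zeros((3, 3), dtype=int)
    for a, p in zip(actual, predicted):
        counts[index[ClassLabel(a)], index[ClassLabel(p)]] += 1
    return ConfusionMatrix3(counts=counts)


def _clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI on a proportion."""
    if n == 0:
        return (float("nan"), float("nan"))
    alpha = 1 - level
    lo = 0.0 if successes == 0 else float(stats.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(stats.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return (lo, hi)


def binary_diagnostics(
    cm: ConfusionMatrix3,
    positive: frozenset[ClassLabel] | set[ClassLabel] = frozenset(
        {ClassLabel.OSTEOPENIA, ClassLabel.OSTEOPOROSIS}
    ),
) -> BinaryDiagnostics:
    """Collapse the 3-class matrix to positive-vs-rest screening diagnostics.

    The default positive set is "low bone density" (osteopenia or
    osteoporosis). Undefined likelihood ratios (division by zero) are
    reported as ``None`` rather than raising.
    """
    positive = {ClassLabel(p) for p in positive}
    if not positive or positive >= set(CLASS_ORDER):
        raise ValueError("positive set must be a non-empty proper subset of the classes")
    pos_idx = [i for i, c in enumerate(CLASS_ORDER) if c in positive]
    neg_idx = [i for i, c in enumerate(CLASS_ORDER) if c not in positive]
    c = cm.counts
    tp = int(c[np.ix_(pos_idx, pos_idx)].sum())
    fn = int(c[np.ix_(pos_idx, neg_idx)].sum())
    fp = int(c[np.ix_(neg_idx, pos_idx)].sum())
    tn = int(c[np.ix_(neg_idx, neg_idx)].sum())
    n = tp + fn + fp + tn
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    acc = (tp + tn) / n if n else float("nan")
    lr_pos = sens / (1 - spec) if spec < 1 else None
    lr_neg = (1 - sens) / spec if spec > 0 else None
    return BinaryDiagnostics(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        sensitivity_ci=_clopper_pearson(tp, tp + fn),
        specificity_ci=_clopper_pearson(tn, tn + fp),
        accuracy_ci=_clopper_pearson(tp + tn, n),
    )


def likelihood_ratios(sensitivity: float, specificity: float) -> tuple[Optional[float], Optional[float]]:
    """LR+ and LR− straight from a (sens, spec) pair, e.g. printed values."""
    lr_pos = sensitivity / (1 - specificity) if specificity < 1 else None
    lr_neg = (1 - sensitivity) / specificity if specificity > 0 else None
    return lr_pos, lr_neg


def percent_agreement(
    labels_a: Sequence[ClassLabel | str], labels_b: Sequence[ClassLabel | str]
) -> float:
    """Fraction of positions with identical labels, as a percentage."""
    if len(labels_a) != len(labels_b):
        raise ValueError("label lists differ in length")
    if len(labels_a) == 0:
        raise ValueError("empty label lists")
    matches = sum(ClassLabel(a) == ClassLabel(b) for a, b in zip(labels_a, labels_b))
    return 100.0 * matches / len(labels_a)
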