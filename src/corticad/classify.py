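"""Feature assembly and RBF-SVM staging of bone density.

Each subject contributes eight features — the minimum, maximum and average
cortical widths of the right and left sides plus the mean normalized
cortical intensity of each side — classified into normal / osteopenia /
osteoporosis by a one-vs-one multiclass SVM with a radial basis kernel.
Evaluation uses stratified k-fold cross-validation with per-fold
standardization and an inner grid search for C and gamma, so no information
leaks from a held-out fold into training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .roi_io import ClassLabel

#: Canonical feature order used for training, persistence and CSV export.
FEATURE_NAMES = (
    "r_min_w", "r_max_w", "r_avg_w",
    "l_min_w", "l_max_w", "l_avg_w",
    "r_texture", "l_texture",
)

FEATURE_SUBSETS: dict[str, tuple[int, ...]] = {
    "width_and_texture": tuple(range(8)),
    "width_only": tuple(range(6)),
    "texture_only": (6, 7),
}

DEFAULT_C_GRID = (0.1, 1.0, 10.0, 100.0)
DEFAULT_GAMMA_GRID = (0.001, 0.01, 0.1, 1.0)
DEFAULT_INNER_K = 3


@dataclass(frozen=True)
class FeatureVector:
    """The 8 classifier inputs, in canonical order."""

    r_min_w: float
    r_max_w: float
    r_avg_w: float
    l_min_w: float
    l_max_w: float
    l_avg_w: float
    r_texture: float
    l_texture: float

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES[:6]:
            if getattr(self, name) <= 0:
                raise ValueError(f"width feature {name} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


@dataclass(frozen=True)
class CvReport:
    """Per-fold and mean accuracy of one k-fold cross-validation run."""

    k: int
    per_fold_accuracy: tuple[float, ...]
    feature_subset: str

    def __post_init__(self) -> None:
        if len(self.per_fold_accuracy) != self.k:
            raise ValueError("need one accuracy per fold")

    @property
    def mean_accuracy(self) -> float:
        return mean_accuracy(self.per_fold_accuracy)


def build_features(
    right: tuple[tuple[float, float, float], float],
    left: tuple[tuple[float, float, float], float],
) -> FeatureVector:
    """Assemble the canonical 8-vector from per-side (widths, texture) pairs,
    widths ordered (min, max, avg)."""
    if right is None or left is None:
        raise ValueError("both sides must be measured")
    (r_min, r_max, r_avg), r_tex = right
    (l_min, l_max, l_avg), l_tex = left
    return FeatureVector(r_min, r_max, r_avg, l_min, l_max, l_avg, r_tex, l_tex)


def _as_matrix(features: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(features, np.ndarray):
        return np.asarray(features, dtype=float)
    return np.stack([f.as_array() for f in features])


def _as_labels(labels: Sequence[ClassLabel] | Sequence[str]) -> np.ndarray:
    return np.array([ClassLabel(l).value for l in labels])


def make_svm_pipeline(C: float = 1.0, gamma: float = 0.1) -> Pipeline:
    """Standardization + one-vs-one RBF-SVM as a single leakage-safe estimator."""
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="rbf", C=C, gamma=gamma, decision_function_shape="ovo")),
    ])


def train_svm(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[ClassLabel] | Sequence[str],
    C: float = 1.0,
    gamma: float = 0.1,
) -> Pipeline:
    """Fit the standardized RBF-SVM; deterministic for fixed inputs."""
    X = _as_matrix(features)
    y = _as_labels(labels)
    if len(X) < 6:
        raise ValueError("need at least 6 training samples")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    model = make_svm_pipeline(C, gamma)
    model.fit(X, y)
    return model


def stratified_folds(
    labels: np.ndarray, k: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded stratified fold assignment; exposed so leakage checks can
    reproduce the exact splits."""
    cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(cv.split(np.zeros((len(labels), 1)), labels))


def cross_validate(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[ClassLabel] | Sequence[str],
    k: int,
    feature_subset: str = "width_and_texture",
    seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    inner_k: int = DEFAULT_INNER_K,
) -> CvReport:
    """Stratified k-fold CV with an inner hyperparameter grid search.

    Per outer fold: standardization and the C/gamma grid search (inner
    ``inner_k``-fold accuracy) use the training split only; the tuned model
    is then scored on the held-out fold. Reproducible for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if feature_subset not in FEATURE_SUBSETS:
        raise ValueError(f"unknown feature subset {feature_subset!r}")
    X = _as_matrix(features)[:, FEATURE_SUBSETS[feature_subset]]
    y = _as_labels(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} members < k={k}; use a smaller k"
        )
    accs = []
    for train_idx, test_idx in stratified_folds(y, k, seed):
        search = GridSearchCV(
            make_svm_pipeline(),
            param_grid={"svm__C": list(c_grid), "svm__gamma": list(gamma_grid)},
            scoring="accuracy",
            cv=StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed),
        )
        search.fit(X[train_idx], y[train_idx])
        accs.append(float(search.best_estimator_.score(X[test_idx], y[test_idx])))
    return CvReport(k=k, per_fold_accuracy=tuple(accs), feature_subset=feature_subset)


def mean_accuracy(accuracies: Sequence[float]) -> float:
    """Arithmetic mean of per-fold accuracies."""
    if len(accuracies) == 0:
        raise ValueError("no accuracies to average")
    return math.fsum(accuracies) / len(accuracies)


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero, as accuracy tables are conventionally
    printed (0.5 at the last digit rounds up, not to even)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
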