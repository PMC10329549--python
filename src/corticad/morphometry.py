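"""Cortical border extraction, polynomial fitting, and perpendicular width.

The upper border of the segmented band is modeled by the polynomial (in
column position) that generalizes best among candidate degrees 1–5 under
5-fold cross-validation — plain least squares alone would always prefer the
highest degree. The cortical width at a sample column is then the distance
travelled from the border point along the inward normal of the fitted curve
until the mask is left: a perpendicular measurement, not a column height,
which matters as soon as the band is oblique (a column height overestimates
a band tilted by θ by the factor 1/cos θ).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .roi_io import CorticalMask, RoiImage

DEFAULT_CANDIDATE_DEGREES = (1, 2, 3, 4, 5)
DEFAULT_MARGIN_FRAC = 0.1
DEFAULT_STEP = 1
_MARCH_STEP = 0.25  # px, sub-pixel marching resolution
_CV_FOLDS = 5


@dataclass(frozen=True)
class BorderCurve:
    """Polynomial model ``row = poly(col)`` of the cortical upper border."""

    coefficients: tuple[float, ...]  # highest degree first
    domain: tuple[int, int]  # (col_min, col_max), inclusive
    sse: float

    def __post_init__(self) -> None:
        if self.domain[1] < self.domain[0]:
            raise ValueError("empty domain")
        if self.sse < 0:
            raise ValueError("sse must be >= 0")

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, col: np.ndarray | float) -> np.ndarray | float:
        return np.polyval(self.coefficients, col)

    def slope(self, col: np.ndarray | float) -> np.ndarray | float:
        return np.polyval(np.polyder(np.asarray(self.coefficients)), col)


@dataclass(frozen=True)
class WidthProfile:
    """Perpendicular widths sampled along the border, with summary stats."""

    samples: tuple[tuple[int, float], ...]  # (col, width px)

    def __post_init__(self) -> None:
        if not self.samples:
            raise ValueError("empty width profile")
        if any(w <= 0 for _, w in self.samples):
            raise ValueError("widths must be positive")

    @property
    def widths(self) -> np.ndarray:
        return np.array([w for _, w in self.samples])

    @property
    def min_width(self) -> float:
        return float(self.widths.min())

    @property
    def max_width(self) -> float:
        return float(self.widths.max())

    @property
    def avg_width(self) -> float:
        return float(self.widths.mean())


def upper_border(mask: CorticalMask) -> list[tuple[int, int]]:
    """Topmost foreground pixel per column, as (col, row); empty columns are
    omitted."""
    px = mask.pixels
    if not px.any():
        raise ValueError("empty mask has no border")
    points = []
    has_fg = px.any(axis=0)
    top_rows = px.argmax(axis=0)
    for col in np.nonzero(has_fg)[0]:
        points.append((int(col), int(top_rows[col])))
    return points


def _cv_sse(cols: np.ndarray, rows: np.ndarray, degree: int) -> float:
    """5-fold cross-validated squared error of a degree-``degree`` fit.

    Folds are assigned by column order (point i sorted by column goes to
    fold i mod 5), a fixed deterministic assignment.
    """
    order = np.argsort(cols, kind="stable")
    cols, rows = cols[order], rows[order]
    folds = np.arange(len(cols)) % _CV_FOLDS
    total = 0.0
    for f in range(_CV_FOLDS):
        train = folds != f
        if train.sum() < degree + 1:
            return np.inf
        coeff = np.polyfit(cols[train], rows[train], degree)
        pred = np.polyval(coeff, cols[~train])
        total += float(np.sum((rows[~train] - pred) ** 2))
    return total


def fit_border_polynomial(
    points: list[tuple[int, int]],
    candidate_degrees: tuple[int, ...] = DEFAULT_CANDIDATE_DEGREES,
) -> BorderCurve:
    """Least-squares polynomial fit with degree chosen by cross-validation.

    Among ``candidate_degrees`` the degree minimizing the 5-fold CV squared
    error is selected (ties favor the lower degree); the returned curve is
    the full-data fit at that degree with its residual SSE.
    """
    if not candidate_degrees:
        raise ValueError("no candidate degrees")
    cols = np.array([c for c, _ in points], dtype=float)
    rows = np.array([r for _, r in points], dtype=float)
    if len(points) < max(candidate_degrees) + 1:
        raise ValueError(
            f"need at least {max(candidate_degrees) + 1} points for degree "
            f"{max(candidate_degrees)}, got {len(points)}"
        )
    if len(np.unique(cols)) < 2:
        raise ValueError("need at least 2 distinct columns")
    scores = {d: _cv_sse(cols, rows, d) for d in candidate_degrees}
    best_score = min(scores.values())
    # near-ties (within float noise of the best score) resolve to the lowest
    # degree, so exactly-polynomial borders select their true degree
    tol = best_score * 1e-9 + 1e-9
    best_degree = min(d for d in candidate_degrees if scores[d] <= best_score + tol)
    coeff = np.polyfit(cols, rows, best_degree)
    sse = float(np.sum((rows - np.polyval(coeff, cols)) ** 2))
    return BorderCurve(
        coefficients=tuple(float(c) for c in coeff),
        domain=(int(cols.min()), int(cols.max())),
        sse=sse,
    )


def width_profile(
    mask: CorticalMask,
    curve: BorderCurve,
    margin_frac: float = DEFAULT_MARGIN_FRAC,
    step: int = DEFAULT_STEP,
) -> WidthProfile:
    """March along the inward border normal at sampled columns.

    At each sample column the tangent slope is the analytic derivative of
    the fitted polynomial; from the border point the unit normal (pointing
    into the band, i.e. toward increasing row) is followed in 0.25 px steps
    with nearest-neighbor mask lookups until the foreground is left. The
    distance travelled is the width. Samples starting on background or whose
    normal leaves the image while still inside foreground are skipped.
    """
    if not (0 <= margin_frac < 0.5):
        raise ValueError("margin_frac must be in [0, 0.5)")
    px = mask.pixels
    h, w = px.shape
    col_min, col_max = curve.domain
    span = col_max - col_min
    lo = col_min + margin_frac * span
    hi = col_max - margin_frac * span
    samples: list[tuple[int, float]] = []
    for col in range(int(np.ceil(lo)), int(np.floor(hi)) + 1, step):
        row0 = float(curve(col))
        slope = float(curve.slope(col))
        norm = np.hypot(slope, 1.0)
        # tangent (dcol, drow) = (1, slope); inward normal points down
        ncol, nrow = -slope / norm, 1.0 / norm
        r, c = row0, float(col)
        ri, ci = int(round(r)), int(round(c))
        if not (0 <= ri < h and 0 <= ci < w) or not px[ri, ci]:
            continue  # curve point off the band: unreliable sample
        dist = 0.0
        truncated = False
        while True:
            r += nrow * _MARCH_STEP
            c += ncol * _MARCH_STEP
            dist += _MARCH_STEP
            ri, ci = int(round(r)), int(round(c))
            if not (0 <= ri < h and 0 <= ci < w):
                truncated = True  # left the image while still in foreground
                break
            if not px[ri, ci]:
                break
        if not truncated and dist > 0:
            # The march starts at the top pixel's center and overshoots the
            # exit by up to one step: add the upper half-pixel, subtract the
            # mean overshoot.
            samples.append((col, dist + 0.5 - _MARCH_STEP / 2))
    if len(samples) < 3:
        raise ValueError(
            f"profile too sparse: only {len(samples)} usable width samples"
        )
    return WidthProfile(samples=tuple(samples))


def measure_side(roi: RoiImage | None, mask: CorticalMask) -> tuple[float, float, float]:
    """Width feature triple (min, max, avg) in px for one side's mask.

    Enclosed holes are filled first: intracortical pores sit inside the
    band and must not terminate the perpendicular march early, which would
    report a pore depth instead of the band thickness. The widths are a
    pure function of the mask; ``roi`` is accepted for interface symmetry
    with the texture stage.
    """
    filled = CorticalMask(ndimage.binary_fill_holes(mask.pixels).astype(np.uint8))
    points = upper_border(filled)
    curve = fit_border_polynomial(points)
    profile = width_profile(filled, curve)
    return profile.min_width, profile.max_width, profile.avg_width
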