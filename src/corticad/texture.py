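"""Intensity normalization and the mean-gray porosity feature.

Panoramic radiographs show uneven illumination, so raw ROI gray levels are
not comparable between patients. Each ROI is therefore re-anchored by an
affine map sending its low/high percentiles to fixed targets before the
texture feature — the mean normalized intensity over the segmented cortical
band — is computed. Porous (low-density) cortical bone contains more dark
regions, so the mean falls as porosity rises.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .roi_io import CorticalMask, RoiImage


@dataclass(frozen=True)
class NormalizationParams:
    """Percentile anchors and gray targets of the affine normalization.

    Percentile anchoring (1st/99th by default) resists the bright cortical
    band and occasional saturated pixels better than min/max scaling.
    """

    low_percentile: float = 1.0
    high_percentile: float = 99.0
    target_low: float = 0.0
    target_high: float = 255.0

    def __post_init__(self) -> None:
        if not (0 <= self.low_percentile < self.high_percentile <= 100):
            raise ValueError("need 0 <= low_percentile < high_percentile <= 100")
        if self.target_low >= self.target_high:
            raise ValueError("target_low must be below target_high")


def normalize_intensity(
    roi: RoiImage | np.ndarray, params: NormalizationParams | None = None
) -> np.ndarray:
    """Affine intensity normalization, clipped to [0, 255].

    The image's low/high percentiles are mapped to the target grays. A
    constant image maps to the midpoint of the target range by convention.
    """
    params = params or NormalizationParams()
    image = roi.pixels if isinstance(roi, RoiImage) else np.asarray(roi, dtype=float)
    lo = np.percentile(image, params.low_percentile)
    hi = np.percentile(image, params.high_percentile)
    if hi == lo:
        return np.full_like(image, (params.target_low + params.target_high) / 2.0, dtype=float)
    scaled = (image - lo) * (params.target_high - params.target_low) / (hi - lo) + params.target_low
    return np.clip(scaled, 0.0, 255.0)


def mean_cortical_intensity(normalized: np.ndarray, mask: CorticalMask) -> float:
    """Arithmetic mean of the normalized image over the mask foreground."""
    normalized = np.asarray(normalized, dtype=float)
    fg = mask.pixels
    if normalized.shape != fg.shape:
        raise ValueError(f"shape mismatch: image {normalized.shape} vs mask {fg.shape}")
    if not fg.any():
        raise ValueError("empty mask: texture feature undefined")
    return float(normalized[fg].mean())


def texture_feature(
    roi: RoiImage,
    mask: CorticalMask,
    params: NormalizationParams | None = None,
    use_mask: bool = True,
    fill_holes: bool = True,
) -> float:
    """The per-side texture feature: normalize, then average over the
    cortical mask (or the whole ROI when ``use_mask`` is off, for ablation).

    Enclosed holes in the mask are filled before averaging by default:
    pores are dark regions *within* the cortical band, and a segmentation
    that excludes them from the mask would otherwise delete exactly the
    pixels that carry the porosity signal, biasing the mean upward for the
    most porous bone.
    """
    normalized = normalize_intensity(roi, params)
    if not use_mask:
        return float(normalized.mean())
    if fill_holes:
        mask = CorticalMask(ndimage.binary_fill_holes(mask.pixels).astype(np.uint8))
    return mean_cortical_intensity(normalized, mask)
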