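"""End-to-end plumbing: run the full stage chain over manifests.

Ties together enhancement, segmentation, morphometry and texture into
per-ROI and per-subject computations used by the CLI, the evaluation
scripts and the tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

from .classify import FeatureVector, build_features
from .line_enhance import LineOperatorParams
from .morphometry import measure_side
from .roi_io import (
    ClassLabel,
    CorticalMask,
    DatasetManifest,
    ManifestRecord,
    RoiImage,
    Side,
    load_mask,
    load_roi,
)
from .srm_segment import DEFAULT_GRADIENT_THRESHOLD, DEFAULT_TOP_K, segment_cortical
from .texture import NormalizationParams, texture_feature

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SideMeasurement:
    mask: CorticalMask
    widths: tuple[float, float, float]  # (min, max, avg) px
    texture: float


def process_roi(
    roi: RoiImage,
    mask: Optional[CorticalMask] = None,
    line_params: Optional[LineOperatorParams] = None,
    gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD,
    top_k: int = DEFAULT_TOP_K,
    norm_params: Optional[NormalizationParams] = None,
    texture_use_mask: bool = True,
) -> SideMeasurement:
    """Segment (unless a mask is supplied), then measure width and texture."""
    if mask is None:
        mask = segment_cortical(roi, line_params, gradient_threshold, top_k)
    widths = measure_side(roi, mask)
    tex = texture_feature(roi, mask, norm_params, use_mask=texture_use_mask)
    return SideMeasurement(mask=mask, widths=widths, texture=tex)


def subject_features(
    record: ManifestRecord,
    use_gt_masks: bool = False,
    **kwargs,
) -> FeatureVector:
    """Compute the 8-feature vector for one manifest record.

    With ``use_gt_masks`` the ground-truth masks from the manifest replace
    the segmentation stage (isolating the measurement stages in tests).
    """
    right = load_roi(record.right_roi_path, Side.RIGHT)
    left = load_roi(record.left_roi_path, Side.LEFT)
    r_mask = l_mask = None
    if use_gt_masks:
        if record.right_mask_path is None or record.left_mask_path is None:
            raise ValueError(f"{record.subject_id}: manifest has no ground-truth masks")
        r_mask = load_mask(record.right_mask_path)
        l_mask = load_mask(record.left_mask_path)
    r = process_roi(right, mask=r_mask, **kwargs)
    l = process_roi(left, mask=l_mask, **kwargs)
    return build_features((r.widths, r.texture), (l.widths, l.texture))


def manifest_features(
    manifest: DatasetManifest,
    use_gt_masks: bool = False,
    on_error: str = "raise",
    **kwargs,
) -> tuple[list[FeatureVector], list[ClassLabel], list[str], list[str]]:
    """Feature vectors and labels for every subject in a manifest.

    ``on_error='skip'`` logs and skips records whose pipeline run fails
    (batch isolation); the failed subject ids are returned last.
    """
    features: list[FeatureVector] = []
    labels: list[ClassLabel] = []
    ids: list[str] = []
    failed: list[str] = []
    for rec in manifest.records:
        try:
            fv = subject_features(rec, use_gt_masks=use_gt_masks, **kwargs)
        except Exception:
            if on_error != "skip":
                raise
            logger.exception("subject %s failed; skipping", rec.subject_id)
            failed.append(rec.subject_id)
            continue
        features.append(fv)
        labels.append(rec.label)
        ids.append(rec.subject_id)
    return features, labels, ids, failed
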