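"""Image and manifest I/O, the ROI data model, and shared coordinate conventions.

Coordinate convention used throughout the package: 0-based ``(row, col)``
indices with row 0 at the image top; crop windows are half-open. Left-side
ROIs are processed as-is (no mirroring) — the pipeline is orientation-agnostic
per side.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

logger = logging.getLogger(__name__)

#: Minimum ROI edge length accepted by library operations. 128x128 is the
#: conventional crop size below the mental foramen, but only the CLI
#: enforces it; small fixtures are legitimate library inputs.
MIN_ROI_SIZE = 32


class Side(str, enum.Enum):
    """Which side of the jaw an ROI was cropped from."""

    LEFT = "left"
    RIGHT = "right"


class ClassLabel(str, enum.Enum):
    """Bone-density class from the WHO T-score bins (DEXA ground truth)."""

    NORMAL = "normal"
    OSTEOPENIA = "osteopenia"
    OSTEOPOROSIS = "osteoporosis"


#: Canonical class order used for confusion matrices and reports.
CLASS_ORDER: tuple[ClassLabel, ...] = (
    ClassLabel.NORMAL,
    ClassLabel.OSTEOPENIA,
    ClassLabel.OSTEOPOROSIS,
)


@dataclass(frozen=True)
class RoiImage:
    """One grayscale ROI crop with its side tag.

    ``pixels`` is a 2-D float array with values in [0, 255]; 8-bit sources
    are kept at their original integer values.
    """

    pixels: np.ndarray
    side: Side
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError(f"ROI pixels must be 2-D, got shape {px.shape}")
        if px.shape[0] < MIN_ROI_SIZE or px.shape[1] < MIN_ROI_SIZE:
            raise ValueError(
                f"ROI must be at least {MIN_ROI_SIZE}x{MIN_ROI_SIZE}, got {px.shape}"
            )
        if not np.all(np.isfinite(px)):
            raise ValueError("ROI contains non-finite pixel values")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("ROI pixel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class CorticalMask:
    """Binary foreground mask of the inferior cortical band."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"mask must be 2-D, got shape {px.shape}")
        uniq = np.unique(px)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0/1")
        object.__setattr__(self, "pixels", px.astype(bool))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def foreground_area(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class ManifestRecord:
    subject_id: str
    left_roi_path: Path
    right_roi_path: Path
    label: ClassLabel
    left_mask_path: Optional[Path] = None
    right_mask_path: Optional[Path] = None


@dataclass(frozen=True)
class DatasetManifest:
    records: tuple[ManifestRecord, ...]
    root: Path = field(default_factory=Path)

    def __len__(self) -> int:
        return len(self.records)

    def class_counts(self) -> dict[ClassLabel, int]:
        counts = {label: 0 for label in CLASS_ORDER}
        for rec in self.records:
            counts[rec.label] += 1
        return counts


def _to_gray(arr: np.ndarray, path: Path) -> np.ndarray:
    """Collapse a channel axis, rejecting genuinely colored images."""
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        rgb = arr[..., :3]
        if not (np.array_equal(rgb[..., 0], rgb[..., 1]) and np.array_equal(rgb[..., 1], rgb[..., 2])):
            raise ValueError(
                f"{path}: color image with unequal channels; convert to grayscale "
                "explicitly rather than relying on a silent luma conversion"
            )
        return rgb[..., 0]
    raise ValueError(f"{path}: unsupported image shape {arr.shape}")


def load_roi(path: str | Path, side: Side | str) -> RoiImage:
    """Load a PNG or TIFF ROI as an 8-bit-range grayscale image.

    16-bit inputs are rescaled linearly onto [0, 255]; color images are
    rejected unless all channels are identical.
    """
    path = Path(path)
    side = Side(side)
    arr = iio.imread(path)
    arr = _to_gray(arr, path)
    if arr.dtype == np.uint16:
        arr = arr.astype(float) * (255.0 / 65535.0)
    elif arr.dtype == np.uint8:
        arr = arr.astype(float)
    else:
        arr = arr.astype(float)
        if arr.size and arr.max() > 255:
            arr = arr * (255.0 / arr.max())
    return RoiImage(pixels=arr, side=side, source_id=str(path))


def write_roi(roi: RoiImage, path: str | Path) -> None:
    """Write an ROI as an 8-bit PNG/TIFF (values rounded to integers)."""
    arr = np.clip(np.rint(roi.pixels), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def load_mask(path: str | Path) -> CorticalMask:
    """Load a binary mask stored as a 0/255 (or 0/1) single-channel image."""
    path = Path(path)
    arr = _to_gray(iio.imread(path), path)
    return CorticalMask(pixels=(np.asarray(arr) > 0).astype(np.uint8))


def write_mask(mask: CorticalMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.pixels.astype(np.uint8) * 255))


def crop_roi(
    image: np.ndarray,
    center_col: int,
    center_row: int,
    size: int,
    side: Side | str = Side.RIGHT,
    source_id: str = "",
) -> RoiImage:
    """Extract a ``size`` x ``size`` crop centered at ``(center_row, center_col)``.

    The window is half-open: rows ``[center_row - size//2, center_row - size//2 + size)``
    and likewise for columns. Windows extending outside the image raise.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("crop source must be a 2-D grayscale image")
    r0 = center_row - size // 2
    c0 = center_col - size // 2
    r1, c1 = r0 + size, c0 + size
    if r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
        raise ValueError(
            f"crop window rows [{r0},{r1}) cols [{c0},{c1}) exceeds image "
            f"shape {image.shape}; no padding is applied"
        )
    crop = image[r0:r1, c0:c1]
    if size < MIN_ROI_SIZE:
        # tiny crops are allowed as raw arrays but not as RoiImage
        return crop  # type: ignore[return-value]
    return RoiImage(pixels=crop, side=Side(side), source_id=source_id)


_MANIFEST_REQUIRED = ("subject_id", "left_roi", "right_roi", "label")
_MANIFEST_OPTIONAL = ("left_mask", "right_mask")


def read_manifest(path: str | Path) -> DatasetManifest:
    """Read and validate a CSV manifest pairing left/right ROIs with labels.

    Paths in the CSV are resolved relative to the manifest's directory.
    """
    path = Path(path)
    root = path.parent
    records: list[ManifestRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        missing = [c for c in _MANIFEST_REQUIRED if c not in fields]
        if missing:
            raise ValueError(f"{path}: manifest missing required columns {missing}")
        for i, row in enumerate(reader, start=2):
            sid = row["subject_id"].strip()
            if sid in seen:
                raise ValueError(f"{path} row {i}: duplicate subject_id {sid!r}")
            seen.add(sid)
            try:
                label = ClassLabel(row["label"].strip())
            except ValueError:
                raise ValueError(
                    f"{path} row {i}: unknown label {row['label']!r}; expected one of "
                    f"{[c.value for c in CLASS_ORDER]}"
                ) from None
            paths = {}
            for col in ("left_roi", "right_roi"):
                p = root / row[col].strip()
                if not p.is_file():
                    raise ValueError(f"{path} row {i}: missing file {p}")
                paths[col] = p
            masks = {}
            for col in _MANIFEST_OPTIONAL:
                val = (row.get(col) or "").strip()
                if val:
                    p = root / val
                    if not p.is_file():
                        raise ValueError(f"{path} row {i}: missing file {p}")
                    masks[col] = p
            records.append(
                ManifestRecord(
                    subject_id=sid,
                    left_roi_path=paths["left_roi"],
                    right_roi_path=paths["right_roi"],
                    label=label,
                    left_mask_path=masks.get("left_mask"),
                    right_mask_path=masks.get("right_mask"),
                )
            )
    manifest = DatasetManifest(records=tuple(records), root=root)
    counts = {k.value: v for k, v in manifest.class_counts().items()}
    logger.info("manifest %s: %d subjects, class counts %s", path, len(manifest), counts)
    return manifest
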