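"""Statistical region merging with automatic seed selection.

The enhanced ROI is first over-segmented into small coherent regions
(gradient watershed with shallow minima suppressed). Two seed regions are
then chosen automatically: the object seed is a large, bright region near
the image center (where the cortical band runs through the ROI), and the
background seed a small, dark region far from the center. Remaining regions
are merged one at a time into whichever class (object or background) is
closest in mean gray; class means are area-weighted and updated after every
merge. The object class, post-processed
to its largest connected component with small holes filled, is the cortical
bone mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.segmentation import watershed

from .line_enhance import LineOperatorParams, multiply_preserve_gray, multiscale_line_response
from .roi_io import CorticalMask, RoiImage

logger = logging.getLogger(__name__)

DEFAULT_GRADIENT_THRESHOLD = 10.0
DEFAULT_TOP_K = 5


@dataclass(frozen=True)
class RegionStats:
    id: int
    area: int
    mean_gray: float
    centroid: tuple[float, float]  # (row, col)


@dataclass(frozen=True)
class RegionPartition:
    """A labeling of every pixel into 4-connected regions with summary stats."""

    label_map: np.ndarray
    regions: tuple[RegionStats, ...]

    def region(self, region_id: int) -> RegionStats:
        for r in self.regions:
            if r.id == region_id:
                return r
        raise KeyError(region_id)


@dataclass(frozen=True)
class SeedAssignment:
    object_seed_id: int
    background_seed_id: int

    def __post_init__(self) -> None:
        if self.object_seed_id == self.background_seed_id:
            raise ValueError("object and background seeds must be distinct regions")


def partition_from_labels(image: np.ndarray, label_map: np.ndarray) -> RegionPartition:
    ids = np.unique(label_map)
    areas = ndimage.sum_labels(np.ones_like(image), label_map, ids)
    means = ndimage.mean(image, label_map, ids)
    centroids = ndimage.center_of_mass(np.ones_like(image), label_map, ids)
    regions = tuple(
        RegionStats(id=int(i), area=int(a), mean_gray=float(m), centroid=(float(cr), float(cc)))
        for i, a, m, (cr, cc) in zip(ids, areas, means, centroids)
    )
    return RegionPartition(label_map=label_map, regions=regions)


def initial_partition(
    image: np.ndarray, gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD
) -> RegionPartition:
    """Over-segment by marker-free watershed on the gradient magnitude.

    Gradient minima shallower than ``gradient_threshold`` are suppressed
    (h-minima) before flooding, which merges regions separated only by weak
    edges. Every pixel belongs to exactly one 4-connected region.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    grad = ndimage.generic_gradient_magnitude(image, ndimage.sobel)
    if np.ptp(grad) == 0:
        label_map = np.ones(image.shape, dtype=int)
    else:
        minima = morphology.h_minima(grad, gradient_threshold)
        markers, n = ndimage.label(minima, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
        if n == 0:
            label_map = np.ones(image.shape, dtype=int)
        else:
            label_map = watershed(grad, markers=markers, connectivity=1)
    return partition_from_labels(image, label_map)


def select_seeds(partition: RegionPartition, top_k: int = DEFAULT_TOP_K) -> SeedAssignment:
    """Pick the object and background seed regions automatically.

    Object candidates are the ``top_k`` regions ranking best jointly on area
    and mean gray (rank-sum of the two descending orderings); the object
    seed is the candidate whose centroid is nearest the image center. The
    background seed minimizes mean gray among regions whose centroid lies
    farther from the center than the median centroid distance (ties: smaller
    area, then smaller id).
    """
    regions = partition.regions
    if len(regions) < 2:
        raise ValueError("degenerate partition: need at least 2 regions to seed")
    center = ((partition.label_map.shape[0] - 1) / 2.0, (partition.label_map.shape[1] - 1) / 2.0)

    def dist_to_center(r: RegionStats) -> float:
        return float(np.hypot(r.centroid[0] - center[0], r.centroid[1] - center[1]))

    by_area = sorted(regions, key=lambda r: (-r.area, r.id))
    by_gray = sorted(regions, key=lambda r: (-r.mean_gray, r.id))
    area_rank = {r.id: i for i, r in enumerate(by_area)}
    gray_rank = {r.id: i for i, r in enumerate(by_gray)}
    candidates = sorted(regions, key=lambda r: (area_rank[r.id] + gray_rank[r.id], r.id))
    candidates = candidates[: max(1, top_k)]
    object_seed = min(candidates, key=lambda r: (dist_to_center(r), r.id))

    distances = sorted(dist_to_center(r) for r in regions)
    median = float(np.median(distances))
    far = [r for r in regions if dist_to_center(r) > median and r.id != object_seed.id]
    if not far:  # all centroids equidistant; fall back to everything but the object seed
        far = [r for r in regions if r.id != object_seed.id]
    background_seed = min(far, key=lambda r: (r.mean_gray, r.area, r.id))
    return SeedAssignment(object_seed_id=object_seed.id, background_seed_id=background_seed.id)


def region_distance(region_mean_gray: float, class_mean_gray: float) -> float:
    """Statistical distance between a region and a class: absolute difference
    of mean grays (the class mean is area-weighted over its member regions)."""
    return abs(float(region_mean_gray) - float(class_mean_gray))


def merge_all(partition: RegionPartition, seeds: SeedAssignment) -> CorticalMask:
    """Agglomerate every region into the object or background class.

    At each step the unlabeled region with the smallest gray distance to
    either class is merged into that class (ties: lowest region id, then
    object class); the receiving class's area-weighted mean is updated.
    Merging is deliberately not restricted to regions touching a labeled
    class: the cortical band typically crosses the whole ROI and seals the
    zone beneath it off from a background seed placed above, so a spatial
    adjacency constraint would force that zone into the wrong class.
    Spatial coherence of the final mask is restored downstream by keeping
    the largest connected component. Terminates with all regions labeled;
    the mask is the union of object-class regions.
    """
    regions = {r.id: r for r in partition.regions}
    for seed_id in (seeds.object_seed_id, seeds.background_seed_id):
        if seed_id not in regions:
            raise ValueError(f"seed region {seed_id} not present in partition")
    # class state: 0 = object, 1 = background
    class_area = [0.0, 0.0]
    class_sum = [0.0, 0.0]
    assignment: dict[int, int] = {}

    def assign(region_id: int, cls: int) -> None:
        r = regions[region_id]
        assignment[region_id] = cls
        class_area[cls] += r.area
        class_sum[cls] += r.area * r.mean_gray

    assign(seeds.object_seed_id, 0)
    assign(seeds.background_seed_id, 1)

    unlabeled = set(regions) - set(assignment)
    while unlabeled:
        best: tuple[float, int, int] | None = None  # (distance, region id, class)
        cmeans = (class_sum[0] / class_area[0], class_sum[1] / class_area[1])
        for rid in unlabeled:
            for cls in (0, 1):
                key = (region_distance(regions[rid].mean_gray, cmeans[cls]), rid, cls)
                if best is None or key < best:
                    best = key
        d, rid, cls = best
        assign(rid, cls)
        unlabeled.discard(rid)
        logger.debug("merged region %d into %s (distance %.3f)",
                     rid, "object" if cls == 0 else "background", d)

    object_ids = np.array([rid for rid, cls in assignment.items() if cls == 0])
    mask = np.isin(partition.label_map, object_ids)
    return CorticalMask(pixels=mask.astype(np.uint8))


def segment_cortical(
    roi: RoiImage,
    params: LineOperatorParams | None = None,
    gradient_threshold: float = DEFAULT_GRADIENT_THRESHOLD,
    top_k: int = DEFAULT_TOP_K,
) -> CorticalMask:
    """Full segmentation stage: enhance, partition, seed, merge, clean.

    The returned mask is the largest 4-connected component of the object
    class with holes of at most 10 px² filled — the width stage requires a
    single solid band.
    """
    response = multiscale_line_response(roi, params)
    enhanced = multiply_preserve_gray(roi, response)
    partition = initial_partition(enhanced, gradient_threshold)
    seeds = select_seeds(partition, top_k)
    mask = merge_all(partition, seeds)
    labeled, n = ndimage.label(mask.pixels, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    if n > 1:
        areas = ndimage.sum_labels(np.ones_like(labeled), labeled, range(1, n + 1))
        keep = int(np.argmax(areas)) + 1
        mask_px = labeled == keep
    else:
        mask_px = mask.pixels.astype(bool)
    mask_px = morphology.remove_small_holes(mask_px, max_size=10)
    return CorticalMask(pixels=mask_px.astype(np.uint8))
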