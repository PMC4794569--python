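"""Cell detection in fluorescence frames.

The classical pipeline: Gaussian smoothing of the green (FITC) channel,
Otsu thresholding, morphological opening, and a watershed on the distance
transform to split touching nuclei. Regions below a minimum area or
touching the frame border are dropped. The same regions serve as both
interphase and mitotic candidates; the distinction is made downstream by
the classifiers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_multiotsu, threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed

from .config import SegmentationConfig
from .contour import trace_boundary
from .types import CellRegion

__all__ = ["segment_cells", "match_regions", "RegionMatch", "region_from_mask"]


def region_from_mask(full_mask: np.ndarray) -> CellRegion:
    """Build a :class:`CellRegion` (bbox, centroid, contour) from a mask."""
    rows, cols = np.nonzero(full_mask)
    if rows.size == 0:
        raise ValueError("cannot build a region from an empty mask")
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
    return CellRegion(
        mask=full_mask,
        bbox=bbox,
        centroid=(float(rows.mean()), float(cols.mean())),
        contour=trace_boundary(full_mask),
        area=int(rows.size),
    )


def _green(image: np.ndarray) -> np.ndarray:
    if image.ndim == 3:
        return image[..., 1].astype(float)
    return image.astype(float)


def segment_cells(
    image: np.ndarray, config: SegmentationConfig | None = None
) -> list[CellRegion]:
    """Detect individual cells in an RGB (or single-channel) frame.

    Returns regions with pairwise-disjoint masks, sorted by the top-left
    corner of their bounding boxes. A featureless frame yields an empty
    list rather than an error.
    """
    cfg = config or SegmentationConfig()
    if image.size == 0:
        raise ValueError("empty image")
    green = _green(image)
    smoothed = gaussian(green, sigma=cfg.smoothing_sigma, preserve_range=True)
    if np.ptp(smoothed) < 1e-9:
        return []
    # the lower threshold of a 3-class Otsu separates background from the
    # dimmest cell compartment even when bright substructures (nucleoli,
    # centromere dots) dominate the histogram's upper mode
    try:
        thresh = float(threshold_multiotsu(smoothed, classes=3)[0])
    except ValueError:  # too few distinct gray values
        thresh = float(threshold_otsu(smoothed))
    binary = smoothed > thresh
    if cfg.opening_radius > 0:
        binary = ndi.binary_opening(binary, structure=disk(cfg.opening_radius))
    binary = ndi.binary_fill_holes(binary)
    if not binary.any():
        return []

    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        distance,
        min_distance=cfg.peak_min_distance,
        labels=binary,
        exclude_border=False,
    )
    if len(peaks) == 0:
        return []
    markers = np.zeros(binary.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-distance, markers, mask=binary)

    h, w = labels.shape
    regions: list[CellRegion] = []
    for lab in range(1, labels.max() + 1):
        mask = labels == lab
        area = int(mask.sum())
        if area < cfg.min_area:
            continue
        rows, cols = np.nonzero(mask)
        touches_border = (
            rows.min() == 0 or cols.min() == 0 or rows.max() == h - 1 or cols.max() == w - 1
        )
        if cfg.drop_border and touches_border:
            continue
        regions.append(region_from_mask(mask))
    regions.sort(key=lambda r: (r.bbox[0], r.bbox[1]))
    return regions


@dataclass
class RegionMatch:
    """Result of greedy one-to-one matching between two region lists."""

    pairs: list[tuple[int, int]]  # (predicted index, truth index)
    matched: int
    missed: int
    spurious: int
    ious: list[float]

    @property
    def recall(self) -> float:
        total = self.matched + self.missed
        return self.matched / total if total else 1.0


def _iou(a: CellRegion, b: CellRegion) -> float:
    ar0, ac0, ar1, ac1 = a.bbox
    br0, bc0, br1, bc1 = b.bbox
    if ar1 <= br0 or br1 <= ar0 or ac1 <= bc0 or bc1 <= ac0:
        return 0.0
    inter = int((a.mask & b.mask).sum())
    if inter == 0:
        return 0.0
    return inter / float(a.area + b.area - inter)


def match_regions(
    predicted: list[CellRegion],
    truth: list[CellRegion],
    iou_threshold: float = 0.5,
) -> RegionMatch:
    """Greedy one-to-one matching by decreasing mask overlap.

    A (predicted, truth) pair matches when its intersection-over-union is
    at least ``iou_threshold``.
    """
    candidates = []
    for i, p in enumerate(predicted):
        for j, t in enumerate(truth):
            iou = _iou(p, t)
            if iou >= iou_threshold:
                candidates.append((iou, i, j))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_pred: set[int] = set()
    used_truth: set[int] = set()
    pairs: list[tuple[int, int]] = []
    ious: list[float] = []
    for iou, i, j in candidates:
        if i in used_pred or j in used_truth:
            continue
        used_pred.add(i)
        used_truth.add(j)
        pairs.append((i, j))
        ious.append(iou)
    matched = len(pairs)
    return RegionMatch(
        pairs=pairs,
        matched=matched,
        missed=len(truth) - matched,
        spurious=len(predicted) - matched,
        ious=ious,
    )
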