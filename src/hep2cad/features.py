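"""The 108-value cell descriptor.

Each segmented cell is described at four gray-level quantizations (256,
128, 64, 32 levels) by 27 features per level — 9 intensity statistics,
8 geometry measures, 8 shape/morphology measures, and 2 gradient-histogram
entropies — for 4 x 27 = 108 values in a fixed, documented order.

Conventions
-----------
* Quantization bins by ``floor(v * levels / 256)``; 256 levels is the
  identity mapping on 8-bit input.
* Entropies are Shannon entropies in bits; empty histogram bins
  contribute zero; a degenerate (all-zero-gradient) histogram has
  entropy 0 by convention.
* Gradients use central differences with one-sided differences at the
  patch border.
* Geometry and shape are computed on a mask re-derived at each
  quantization level (quantized value > 0 within the cell mask), so they
  legitimately vary across levels; if quantization annihilates the cell
  the segmentation mask is used unchanged.
* The ninth intensity feature is the median quantized level, a robust
  central-tendency companion to the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from skimage.morphology import convex_hull_image

from .contour import chain_perimeter, trace_boundary
from .types import CellRegion

__all__ = [
    "QUANTIZATION_LEVELS",
    "FEATURE_NAMES",
    "FeatureVector",
    "quantize",
    "intensity_features",
    "geometry_features",
    "shape_features",
    "descriptor_features",
    "extract_cell_features",
]

QUANTIZATION_LEVELS: tuple[int, ...] = (256, 128, 64, 32)

#: number of orientation bins in the HOG entropy (unsigned, 0-180 deg)
HOG_BINS = 9
#: number of magnitude bins in the HAG entropy
HAG_BINS = 16
#: box sizes for the contour box-counting dimension
FRACTAL_BOX_SIZES = (2, 4, 8, 16, 32)

_INTENSITY_NAMES = (
    "mean",
    "sd",
    "sd_over_mean",
    "entropy",
    "moment_of_inertia",
    "skewness",
    "kurtosis",
    "contour_gradient_entropy",
    "median",
)
_GEOMETRY_NAMES = (
    "radius_mean",
    "radius_sd",
    "radius_max",
    "radius_sd_over_mean",
    "circularity",
    "anisotropy",
    "fractal_index",
    "eccentricity",
)
_SHAPE_NAMES = (
    "area",
    "perimeter",
    "convex_area",
    "convex_deficiency",
    "solidity",
    "compactness",
    "roundness",
    "euler_number",
)
_DESCRIPTOR_NAMES = ("hog_entropy", "hag_entropy")

FEATURE_NAMES: tuple[str, ...] = tuple(
    f"L{levels}.{group}.{name}"
    for levels in QUANTIZATION_LEVELS
    for group, names in (
        ("intensity", _INTENSITY_NAMES),
        ("geometry", _GEOMETRY_NAMES),
        ("shape", _SHAPE_NAMES),
        ("descriptor", _DESCRIPTOR_NAMES),
    )
    for name in names
)
assert len(FEATURE_NAMES) == 108


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 108-value descriptor of one cell."""

    values: np.ndarray

    names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(FEATURE_NAMES),):
            raise ValueError(
                f"feature vector must have exactly {len(FEATURE_NAMES)} "
                f"values, got shape {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            bad = [FEATURE_NAMES[i] for i in np.flatnonzero(~np.isfinite(values))]
            raise ValueError(f"non-finite feature values: {bad}")
        object.__setattr__(self, "values", values)

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def __len__(self) -> int:
        return len(self.values)


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Map 8-bit gray values onto ``levels`` bins: ``floor(v * levels / 256)``."""
    if levels not in QUANTIZATION_LEVELS:
        raise ValueError(f"levels must be one of {QUANTIZATION_LEVELS}, got {levels}")
    gray = np.asarray(gray)
    if gray.size and (gray.min() < 0 or gray.max() > 255):
        raise ValueError("input gray values must lie in [0, 255]")
    return (gray.astype(np.int64) * levels) // 256


def _histogram_entropy(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of a count histogram; empty bins contribute 0."""
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return mask & ~eroded


def _gradients(patch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(d/drow, d/dcol) by central differences, one-sided at the border."""
    patch = patch.astype(float)
    if patch.shape[0] < 2 or patch.shape[1] < 2:
        z = np.zeros_like(patch)
        return z, z
    gr, gc = np.gradient(patch)
    return gr, gc


def intensity_features(quantized: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Nine first-order statistics of the quantized levels under ``mask``.

    Returns, in order: mean, sd, sd/mean, level-histogram entropy,
    moment of inertia about the intensity centroid, skewness, excess
    kurtosis, entropy of the gradient-magnitude histogram on the mask
    boundary, and the median level.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("intensity features require a non-empty mask")
    values = np.asarray(quantized, dtype=float)[mask]
    mean = float(values.mean())
    sd = float(values.std())
    sd_over_mean = sd / mean if mean != 0 else 0.0
    counts = np.bincount(np.asarray(quantized)[mask].astype(np.int64))
    entropy = _histogram_entropy(counts)

    rows, cols = np.nonzero(mask)
    weights = values
    wsum = weights.sum()
    if wsum > 0:
        cr = float((rows * weights).sum() / wsum)
        cc = float((cols * weights).sum() / wsum)
        d2 = (rows - cr) ** 2 + (cols - cc) ** 2
        moment = float((weights * d2).sum() / wsum)
    else:
        moment = 0.0

    if sd > 0:
        skewness = float(stats.skew(values))
        kurt = float(stats.kurtosis(values))  # Fisher (excess)
    else:
        skewness = 0.0
        kurt = 0.0

    gr, gc = _gradients(np.asarray(quantized, dtype=float))
    magnitude = np.hypot(gr, gc)
    boundary = _boundary_pixels(mask)
    bmag = magnitude[boundary]
    if bmag.size == 0 or bmag.max() == 0:
        contour_grad_entropy = 0.0
    else:
        hist, _ = np.histogram(bmag, bins=HAG_BINS, range=(0.0, float(bmag.max())))
        contour_grad_entropy = _histogram_entropy(hist)

    median = float(np.median(values))
    return np.array(
        [mean, sd, sd_over_mean, entropy, moment, skewness, kurt, contour_grad_entropy, median]
    )


def _axis_lengths(mask: np.ndarray) -> tuple[float, float]:
    """(major, minor) axis lengths of the second-moment (best-fit) ellipse."""
    rows, cols = np.nonzero(mask)
    coords = np.vstack([rows, cols]).astype(float)
    cov = np.cov(coords) if coords.shape[1] > 1 else np.zeros((2, 2))
    eigvals = np.sort(np.linalg.eigvalsh(np.atleast_2d(cov)))[::-1]
    eigvals = np.clip(eigvals, 0.0, None)
    return 4.0 * float(np.sqrt(eigvals[0])), 4.0 * float(np.sqrt(eigvals[1]))


def _box_counting_dimension(contour: np.ndarray) -> float:
    pts = np.asarray(contour, dtype=float)
    pts = pts - pts.min(axis=0)
    sizes = np.asarray(FRACTAL_BOX_SIZES, dtype=float)
    counts = []
    for s in sizes:
        boxes = np.unique(np.floor(pts / s), axis=0)
        counts.append(len(boxes))
    counts = np.asarray(counts, dtype=float)
    slope = np.polyfit(np.log(1.0 / sizes), np.log(counts), 1)[0]
    return float(slope)


def geometry_features(
    mask: np.ndarray, contour: np.ndarray | None = None
) -> np.ndarray:
    """Eight radial/elliptical measures of a single connected region.

    Returns, in order: mean, sd and max of the centroid-to-contour radii,
    sd/mean of the radii, circularity (4*pi*A/P^2), anisotropy
    (1 - minor/major axis), box-counting fractal index of the contour,
    and the eccentricity of the best-fit ellipse.
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area < 4:
        raise ValueError("geometry features require a region of at least 4 px")
    n_components = ndi.label(mask, structure=np.ones((3, 3)))[1]
    if n_components != 1:
        raise ValueError("geometry features require a single connected region")
    if contour is None:
        contour = trace_boundary(mask)
    rows, cols = np.nonzero(mask)
    centroid = np.array([rows.mean(), cols.mean()])
    radii = np.linalg.norm(np.asarray(contour, dtype=float) - centroid, axis=1)
    r_mean = float(radii.mean())
    r_sd = float(radii.std())
    r_max = float(radii.max())
    r_ratio = r_sd / r_mean if r_mean != 0 else 0.0
    perimeter = chain_perimeter(contour)
    circularity = 4.0 * np.pi * area / perimeter**2 if perimeter > 0 else 0.0
    major, minor = _axis_lengths(mask)
    anisotropy = 1.0 - (minor / major) if major > 0 else 0.0
    fractal = _box_counting_dimension(contour)
    eccentricity = float(np.sqrt(max(0.0, 1.0 - (minor / major) ** 2))) if major > 0 else 0.0
    return np.array(
        [r_mean, r_sd, r_max, r_ratio, circularity, anisotropy, fractal, eccentricity]
    )


def shape_features(
    mask: np.ndarray, contour: np.ndarray | None = None
) -> np.ndarray:
    """Eight morphological measures of a region.

    Returns, in order: area, perimeter (8-connected chain length,
    diagonal steps sqrt 2), convex area, convex deficiency, solidity,
    compactness (P^2/A), roundness (4A / (pi * major_axis^2)), and the
    Euler number (8-connected foreground, 4-connected background).
    """
    mask = np.asarray(mask, dtype=bool)
    area = int(mask.sum())
    if area == 0:
        raise ValueError("shape features require a non-empty mask")
    if contour is None:
        contour = trace_boundary(mask)
    perimeter = chain_perimeter(contour)
    rows, cols = np.nonzero(mask)
    r0, c0, r1, c1 = rows.min(), cols.min(), rows.max() + 1, cols.max() + 1
    hull = convex_hull_image(mask[r0:r1, c0:c1])
    convex_area = int(hull.sum())
    convex_deficiency = (convex_area - area) / convex_area if convex_area else 0.0
    solidity = area / convex_area if convex_area else 0.0
    compactness = perimeter**2 / area
    major, _ = _axis_lengths(mask)
    roundness = 4.0 * area / (np.pi * major**2) if major > 0 else 0.0
    # Euler number with 8-connected foreground / 4-connected background
    n_fg = ndi.label(mask, structure=np.ones((3, 3)))[1]
    padded_bg = np.pad(~mask, 1, constant_values=True)
    n_bg = ndi.label(padded_bg, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))[1]
    euler = float(n_fg - (n_bg - 1))
    return np.array(
        [area, perimeter, convex_area, convex_deficiency, solidity, compactness, roundness, euler]
    )


def descriptor_features(quantized: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Entropies of the oriented- and amplitude-gradient histograms.

    HOG: 9-bin unsigned-orientation histogram over [0, 180) degrees,
    weighted by gradient magnitude. HAG: 16-bin histogram of gradient
    magnitudes over [0, max magnitude]. Both are computed on mask pixels
    and summarised by their Shannon entropy in bits.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0 or rows.max() - rows.min() < 1 or cols.max() - cols.min() < 1:
        raise ValueError("descriptor features require a mask of at least 2x2 extent")
    gr, gc = _gradients(np.asarray(quantized, dtype=float))
    magnitude = np.hypot(gr, gc)[mask]
    if magnitude.max() == 0:
        return np.array([0.0, 0.0])
    orientation = np.degrees(np.arctan2(gr, gc))[mask] % 180.0
    hog, _ = np.histogram(
        orientation, bins=HOG_BINS, range=(0.0, 180.0), weights=magnitude
    )
    hag, _ = np.histogram(magnitude, bins=HAG_BINS, range=(0.0, float(magnitude.max())))
    return np.array([_histogram_entropy(hog), _histogram_entropy(hag)])


def _level_mask(quantized: np.ndarray, local_mask: np.ndarray) -> np.ndarray:
    """Mask for geometry/shape at one level: quantized > 0 within the cell.

    Keeps the largest connected component (geometry requires a single
    region); falls back to the segmentation mask when quantization
    annihilates the cell or leaves fewer than 4 px.
    """
    derived = (quantized > 0) & local_mask
    if derived.sum() >= 4:
        labels, n = ndi.label(derived, structure=np.ones((3, 3)))
        if n > 1:
            largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
            derived = labels == largest
        if derived.sum() >= 4:
            return derived
    return local_mask


def extract_cell_features(image: np.ndarray, region: CellRegion) -> FeatureVector:
    """Compute the full 108-value descriptor for one cell.

    The green channel is cropped to the region's bounding box and
    quantized at 256, 128, 64 and 32 levels; the 27 per-level features
    are concatenated levels-major in the group order intensity,
    geometry, shape, descriptor. All quantities are mask-relative, so
    the descriptor is invariant to where the cell sits in the frame.
    """
    r0, c0, r1, c1 = region.bbox
    if r0 < 0 or c0 < 0 or r1 > image.shape[0] or c1 > image.shape[1]:
        raise ValueError("region bounding box exceeds the image bounds")
    green = image[..., 1] if image.ndim == 3 else image
    crop = np.asarray(green[r0:r1, c0:c1], dtype=float)
    local = region.local_mask()
    blocks: list[np.ndarray] = []
    for levels in QUANTIZATION_LEVELS:
        q = quantize(crop, levels)
        geo_mask = _level_mask(q, local)
        geo_contour = trace_boundary(geo_mask)
        blocks.append(intensity_features(q, local))
        blocks.append(geometry_features(geo_mask, geo_contour))
        blocks.append(shape_features(geo_mask, geo_contour))
        blocks.append(descriptor_features(q, local))
    return FeatureVector(np.concatenate(blocks))
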