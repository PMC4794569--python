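"""Synthetic HEp-2 indirect-immunofluorescence well generator.

Real ANA slides show interphase nuclei whose FITC fluorescence is
distributed according to the serum's autoantibody specificity, plus a few
mitotic figures whose chromosome mass is either dark against a bright
cell body (negative mitosis) or the single bright structure in the cell
(positive mitosis). This module emulates those phenomenologies well
enough to exercise a full segmentation / feature / classification
pipeline with exact ground truth:

* each of the seven staining patterns keys on the one visual trait the
  standard ANA nomenclature attributes to it (uniform fill, fine or
  coarse granularity, a handful of bright nucleoli, dozens of discrete
  centromere dots, a few nuclear dots, a bright nuclear rim);
* the three intensity classes scale a cell's unit texture by a class
  amplitude, so brightness is strictly monotone negative < intermediate
  < positive for a fixed texture seed;
* fluorescence lives in the green channel; red and blue receive a small
  configurable bleed, matching FITC imagery;
* images are composed by rejection-sampling non-overlapping cells onto a
  constant background with additive Gaussian camera noise.

Every generator is a pure function of its arguments including the seed.
Negative wells contain dim but morphologically visible cells rather than
empty frames, mirroring real negative sera. Photorealism is explicitly
out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import SimulatorConfig
from .contour import trace_boundary
from .types import (
    PATTERNS,
    CellRegion,
    IntensityClass,
    MitosisType,
    StainingPattern,
    WellRecord,
)

__all__ = [
    "ImageSpec",
    "SyntheticImage",
    "generate_cell",
    "generate_mitotic_cell",
    "generate_image",
    "generate_dataset",
    "write_image",
    "write_sidecar",
    "load_sidecar",
    "MANIFEST_COLUMNS",
]

MANIFEST_COLUMNS = [
    "well_id",
    "image_path",
    "image_index",
    "intensity_label",
    "pattern_label",
    "seed",
]


@dataclass(frozen=True)
class ImageSpec:
    """Full recipe for one synthetic image."""

    width: int = 320
    height: int = 320
    n_interphase: int = 8
    n_mitotic: int = 1
    pattern: StainingPattern = StainingPattern.HOMOGENEOUS
    intensity: IntensityClass = IntensityClass.POSITIVE
    mitosis_type: MitosisType = MitosisType.NEGATIVE_MITOSIS
    noise_sd: float = 4.0
    background_level: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 64 or self.height < 64:
            raise ValueError("image dimensions must be at least 64 px")
        if self.n_interphase < 0 or self.n_mitotic < 0:
            raise ValueError("cell counts must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class SyntheticImage:
    """A rendered frame plus its exact ground truth."""

    pixels: np.ndarray  # (H, W, 3) uint8
    truth_cells: list[CellRegion]
    spec: ImageSpec


def _intensity_amplitude(intensity: IntensityClass, cfg: SimulatorConfig) -> float:
    return {
        IntensityClass.NEGATIVE: cfg.amplitude_negative,
        IntensityClass.INTERMEDIATE: cfg.amplitude_intermediate,
        IntensityClass.POSITIVE: cfg.amplitude_positive,
    }[intensity]


def _ellipse_mask(
    shape: tuple[int, int],
    center: tuple[float, float],
    radii: tuple[float, float],
    angle: float,
) -> np.ndarray:
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    dr = rr - center[0]
    dc = cc - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dr * ca + dc * sa
    v = -dr * sa + dc * ca
    return (u / radii[0]) ** 2 + (v / radii[1]) ** 2 <= 1.0


def _scatter_dots(
    texture: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    n_dots: int,
    radius_range: tuple[float, float],
    level: float,
    margin: float = 1.0,
) -> None:
    """Stamp ``n_dots`` bright disks of the given radius range into ``texture``."""
    rows, cols = np.nonzero(mask)
    if rows.size == 0 or n_dots <= 0:
        return
    rr, cc = np.mgrid[0 : mask.shape[0], 0 : mask.shape[1]]
    for _ in range(n_dots):
        i = rng.integers(rows.size)
        r0, c0 = float(rows[i]), float(cols[i])
        rad = float(rng.uniform(*radius_range))
        dot = (rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2
        texture[dot & mask] = level


def _interior_distance(mask: np.ndarray) -> np.ndarray:
    from scipy.ndimage import distance_transform_edt

    return distance_transform_edt(mask)


def _unit_texture(
    pattern: StainingPattern,
    mask: np.ndarray,
    rng: np.random.Generator,
    base: float,
) -> np.ndarray:
    """Pattern-specific texture in [0, 1] over ``mask`` (0 outside)."""
    area = int(mask.sum())
    tex = np.zeros(mask.shape, dtype=float)
    if pattern is StainingPattern.HOMOGENEOUS:
        tex[mask] = 1.0
    elif pattern is StainingPattern.FINE_SPECKLED:
        tex[mask] = base
        _scatter_dots(tex, mask, rng, n_dots=max(area // 6, 20), radius_range=(0.5, 1.0), level=1.0)
    elif pattern is StainingPattern.COARSE_SPECKLED:
        tex[mask] = base
        _scatter_dots(tex, mask, rng, n_dots=max(area // 70, 6), radius_range=(1.5, 3.0), level=1.0)
    elif pattern is StainingPattern.NUCLEOLAR:
        tex[mask] = base
        n_blobs = int(rng.integers(1, 6))
        # interior-only placement keeps every nucleolus fully inside
        core = _interior_distance(mask) > 6.0
        target = core if core.any() else mask
        _scatter_dots(tex, target, rng, n_dots=n_blobs, radius_range=(3.4, 5.0), level=1.0)
    elif pattern is StainingPattern.CENTROMERE:
        tex[mask] = base
        n_dots = int(rng.integers(30, 61))
        _scatter_dots(tex, mask, rng, n_dots=n_dots, radius_range=(1.0, 1.5), level=1.0)
    elif pattern is StainingPattern.NUCLEAR_DOTS:
        tex[mask] = base
        n_dots = int(rng.integers(2, 11))
        core = _interior_distance(mask) > 4.0
        target = core if core.any() else mask
        _scatter_dots(tex, target, rng, n_dots=n_dots, radius_range=(1.8, 2.5), level=1.0)
    elif pattern is StainingPattern.NUCLEAR_PORE_COMPLEX:
        dist = _interior_distance(mask)
        tex[mask] = 0.3
        tex[(dist > 0) & (dist <= 2.5)] = 1.0
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown staining pattern {pattern!r}")
    return tex


def generate_cell(
    pattern: StainingPattern | str,
    intensity: IntensityClass | str,
    radius: float,
    seed: int,
    config: SimulatorConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one interphase nucleus.

    Returns ``(patch, mask)`` where ``patch`` is a float gray-level image
    of the noiseless fluorescence signal and ``mask`` is the elliptical
    nucleus footprint. Mean interior brightness is set by the intensity
    class amplitude, so for a fixed seed it is strictly monotone over
    negative < intermediate < positive. Deterministic given the seed.
    """
    cfg = config or SimulatorConfig()
    pattern = StainingPattern.from_label(str(pattern)) if not isinstance(pattern, StainingPattern) else pattern
    intensity = IntensityClass.from_label(str(intensity)) if not isinstance(intensity, IntensityClass) else intensity
    if radius < 8:
        raise ValueError("cell radius must be at least 8 px")
    rng = np.random.default_rng(seed)
    side = int(2 * radius + 6)
    center = (side / 2.0, side / 2.0)
    axis_ratio = float(rng.uniform(0.75, 1.0))
    angle = float(rng.uniform(0, np.pi))
    mask = _ellipse_mask((side, side), center, (radius, radius * axis_ratio), angle)
    tex = _unit_texture(pattern, mask, rng, base=cfg.texture_base_fraction)
    amp = _intensity_amplitude(intensity, cfg)
    patch = np.clip(tex * amp, 0.0, 255.0)
    return patch, mask


def generate_mitotic_cell(
    mitosis_type: MitosisType | str,
    pattern: StainingPattern | str,
    seed: int,
    radius: float = 16.0,
    intensity: IntensityClass | str = IntensityClass.POSITIVE,
    config: SimulatorConfig | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one mitotic figure.

    Returns ``(patch, body_mask, mass_mask)``: the cell body (chromosome
    mass excluded) and the compact central collapsed-chromosome mass. A
    negative mitosis has a fluorescent body and dark mass; a positive
    mitosis the opposite.
    """
    cfg = config or SimulatorConfig()
    mitosis_type = (
        MitosisType.from_label(str(mitosis_type))
        if not isinstance(mitosis_type, MitosisType)
        else mitosis_type
    )
    StainingPattern.from_label(str(pattern))  # validate vocabulary
    intensity = IntensityClass.from_label(str(intensity)) if not isinstance(intensity, IntensityClass) else intensity
    rng = np.random.default_rng(seed)
    side = int(2 * radius + 6)
    center = (side / 2.0, side / 2.0)
    axis_ratio = float(rng.uniform(0.8, 1.0))
    angle = float(rng.uniform(0, np.pi))
    cell = _ellipse_mask((side, side), center, (radius, radius * axis_ratio), angle)
    jitter = rng.uniform(-1.5, 1.5, size=2)
    # the collapsed chromosome mass occupies a large central fraction of
    # the cell so that it remains detectable on its own when the weakly
    # fluorescent body of a positive mitosis falls below threshold
    mass = _ellipse_mask(
        (side, side),
        (center[0] + jitter[0], center[1] + jitter[1]),
        (0.55 * radius, 0.50 * radius),
        float(rng.uniform(0, np.pi)),
    )
    mass &= cell
    body = cell & ~mass
    if mitosis_type is MitosisType.NEGATIVE_MITOSIS:
        body_level, mass_level = 0.95, 0.25
    else:
        body_level, mass_level = 0.28, 0.95
    tex = np.zeros((side, side), dtype=float)
    tex[body] = body_level
    tex[mass] = mass_level
    amp = _intensity_amplitude(intensity, cfg)
    patch = np.clip(tex * amp, 0.0, 255.0)
    return patch, body, mass


def _region_from_mask(
    full_mask: np.ndarray,
    pattern: StainingPattern | None,
    mitosis: MitosisType | None,
) -> CellRegion:
    rows, cols = np.nonzero(full_mask)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
    centroid = (float(rows.mean()), float(cols.mean()))
    contour = trace_boundary(full_mask)
    return CellRegion(
        mask=full_mask,
        bbox=bbox,
        centroid=centroid,
        contour=contour,
        area=int(rows.size),
        pattern=pattern,
        mitosis=mitosis,
    )


def generate_image(
    spec: ImageSpec, config: SimulatorConfig | None = None
) -> SyntheticImage:
    """Compose a full frame from ``spec``.

    Cells are placed by rejection sampling with a bounded number of
    attempts; their masks never overlap. Raises if the requested density
    cannot be placed.
    """
    cfg = config or SimulatorConfig()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    signal = np.zeros((h, w), dtype=float)
    occupied = np.zeros((h, w), dtype=bool)
    truth: list[CellRegion] = []

    plan: list[tuple[str, int]] = [("interphase", i) for i in range(spec.n_interphase)]
    plan += [("mitotic", i) for i in range(spec.n_mitotic)]

    for kind, _ in plan:
        if kind == "mitotic":
            # mitotic figures are rounder and slightly larger than
            # interphase nuclei; this also keeps the chromosome mass above
            # the downstream minimum-area filter on its own
            radius = float(rng.uniform(cfg.cell_radius_max - 2, cfg.cell_radius_max + 2))
        else:
            radius = float(rng.uniform(cfg.cell_radius_min, cfg.cell_radius_max))
        cell_seed = int(rng.integers(0, 2**31 - 1))
        if kind == "interphase":
            patch, mask = generate_cell(spec.pattern, spec.intensity, radius, cell_seed, cfg)
            mitosis = None
        else:
            patch, body, mass = generate_mitotic_cell(
                spec.mitosis_type, spec.pattern, cell_seed, radius, spec.intensity, cfg
            )
            mask = body | mass
            mitosis = spec.mitosis_type
        ph, pw = mask.shape
        placed = False
        for _ in range(cfg.max_placement_attempts):
            r0 = int(rng.integers(0, h - ph + 1))
            c0 = int(rng.integers(0, w - pw + 1))
            window = occupied[r0 : r0 + ph, c0 : c0 + pw]
            if not (window & mask).any():
                occupied[r0 : r0 + ph, c0 : c0 + pw] |= mask
                signal[r0 : r0 + ph, c0 : c0 + pw][mask] = patch[mask]
                full = np.zeros((h, w), dtype=bool)
                full[r0 : r0 + ph, c0 : c0 + pw] = mask
                truth.append(_region_from_mask(full, spec.pattern, mitosis))
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place cell {len(truth) + 1} of "
                f"{len(plan)} after {cfg.max_placement_attempts} attempts: "
                f"requested density exceeds the {w}x{h} frame capacity"
            )

    rgb = np.empty((h, w, 3), dtype=float)
    rgb[..., 1] = signal + spec.background_level
    rgb[..., 0] = cfg.channel_bleed * signal + 0.5 * spec.background_level
    rgb[..., 2] = cfg.channel_bleed * signal + 0.5 * spec.background_level
    if spec.noise_sd > 0:
        rgb += rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    pixels = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)
    return SyntheticImage(pixels=pixels, truth_cells=truth, spec=spec)


# ---------------------------------------------------------------------------
# dataset emission


def _mask_rle(local_mask: np.ndarray) -> list[int]:
    """Row-major run-length encoding, alternating (zeros, ones, zeros, ...)."""
    flat = np.asarray(local_mask, dtype=np.uint8).ravel()
    if flat.size == 0:
        return []
    changes = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], changes, [flat.size]])
    runs = np.diff(bounds).tolist()
    if flat[0] == 1:  # convention: first run counts zeros
        runs = [0] + runs
    return [int(r) for r in runs]


def rle_decode(runs: list[int], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    pos = 0
    for i, run in enumerate(runs):
        if i % 2 == 1:
            flat[pos : pos + run] = True
        pos += run
    return flat.reshape(shape)


def write_sidecar(path: Path, image: SyntheticImage) -> None:
    """Ground-truth JSON sidecar: bbox, mask RLE, pattern, mitosis per cell."""
    cells = []
    for region in image.truth_cells:
        r0, c0, r1, c1 = region.bbox
        cells.append(
            {
                "bbox": [r0, c0, r1, c1],
                "mask_rle": _mask_rle(region.mask[r0:r1, c0:c1]),
                "centroid": [region.centroid[0], region.centroid[1]],
                "area": region.area,
                "pattern": region.pattern.value if region.pattern else None,
                "mitosis": region.mitosis.value if region.mitosis else None,
            }
        )
    payload = {
        "width": image.spec.width,
        "height": image.spec.height,
        "intensity": image.spec.intensity.value,
        "cells": cells,
    }
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_sidecar(path: Path) -> list[CellRegion]:
    """Reconstruct ground-truth regions from a sidecar file."""
    payload = json.loads(Path(path).read_text())
    h, w = payload["height"], payload["width"]
    regions = []
    for cell in payload["cells"]:
        r0, c0, r1, c1 = cell["bbox"]
        full = np.zeros((h, w), dtype=bool)
        full[r0:r1, c0:c1] = rle_decode(cell["mask_rle"], (r1 - r0, c1 - c0))
        regions.append(
            _region_from_mask(
                full,
                StainingPattern(cell["pattern"]) if cell["pattern"] else None,
                MitosisType(cell["mitosis"]) if cell["mitosis"] else None,
            )
        )
    return regions


def write_image(path: Path, pixels: np.ndarray, cfg: SimulatorConfig) -> None:
    if cfg.image_format == "jpeg":
        iio.imwrite(path, pixels, quality=cfg.jpeg_quality)
    else:
        iio.imwrite(path, pixels)


def generate_dataset(
    n_wells_per_class: dict[StainingPattern | str, int],
    negative_fraction: float | None = None,
    seed: int = 0,
    out_dir: str | Path = ".",
    config: SimulatorConfig | None = None,
) -> pd.DataFrame:
    """Emit a labelled synthetic dataset of wells to ``out_dir``.

    Positive wells carry three images sharing one pattern and one
    non-negative intensity; negative wells carry a single dim-cell image.
    The number of negative wells is set so they form ``negative_fraction``
    of all wells (rounded). Returns the manifest, which is also written to
    ``out_dir / "manifest.csv"`` alongside one ground-truth JSON sidecar
    per image. Byte-identical outputs for identical arguments.
    """
    cfg = config or SimulatorConfig()
    if negative_fraction is None:
        negative_fraction = cfg.negative_fraction
    if not 0 <= negative_fraction < 1:
        raise ValueError("negative_fraction must be in [0, 1)")
    requests: list[tuple[StainingPattern, int]] = []
    for key, count in n_wells_per_class.items():
        pat = key if isinstance(key, StainingPattern) else StainingPattern.from_label(str(key))
        if count < 0:
            raise ValueError("well counts must be non-negative")
        requests.append((pat, int(count)))
    requests.sort(key=lambda item: list(PATTERNS).index(item[0]))

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    images_dir = out_dir / "images"
    images_dir.mkdir(exist_ok=True)

    n_positive = sum(count for _, count in requests)
    n_negative = int(round(n_positive * negative_fraction / (1.0 - negative_fraction)))

    rows: list[dict] = []
    well_idx = 0

    def emit_image(
        well_id: str,
        image_index: int,
        spec: ImageSpec,
        intensity_label: str,
        pattern_label: str,
    ) -> None:
        image = generate_image(spec, cfg)
        ext = "jpg" if cfg.image_format == "jpeg" else "png"
        rel = f"images/{well_id}_{image_index}.{ext}"
        write_image(out_dir / rel, image.pixels, cfg)
        write_sidecar(out_dir / (rel + ".truth.json"), image)
        rows.append(
            {
                "well_id": well_id,
                "image_path": rel,
                "image_index": image_index,
                "intensity_label": intensity_label,
                "pattern_label": pattern_label,
                "seed": spec.seed,
            }
        )

    for pattern, count in requests:
        for _ in range(count):
            well_id = f"W{well_idx:04d}"
            well_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=seed, spawn_key=(well_idx,))
            )
            intensity = (
                IntensityClass.INTERMEDIATE
                if well_rng.random() < 0.5
                else IntensityClass.POSITIVE
            )
            for image_index in range(3):
                n_mitotic = cfg.n_mitotic
                if cfg.guarantee_mitosis:
                    n_mitotic = max(1, n_mitotic)
                spec = ImageSpec(
                    width=cfg.width,
                    height=cfg.height,
                    n_interphase=cfg.n_interphase,
                    n_mitotic=n_mitotic,
                    pattern=pattern,
                    intensity=intensity,
                    mitosis_type=(
                        MitosisType.NEGATIVE_MITOSIS
                        if well_rng.random() < 0.5
                        else MitosisType.POSITIVE_MITOSIS
                    ),
                    noise_sd=cfg.noise_sd,
                    background_level=cfg.background_level,
                    seed=int(well_rng.integers(0, 2**31 - 1)),
                )
                emit_image(well_id, image_index, spec, intensity.value, pattern.value)
            well_idx += 1

    for k in range(n_negative):
        well_id = f"W{well_idx:04d}"
        well_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(well_idx,))
        )
        # texture pattern of a negative well is irrelevant; vary it anyway
        pattern = PATTERNS[int(well_rng.integers(len(PATTERNS)))]
        spec = ImageSpec(
            width=cfg.width,
            height=cfg.height,
            n_interphase=cfg.n_interphase,
            n_mitotic=cfg.n_mitotic,
            pattern=pattern,
            intensity=IntensityClass.NEGATIVE,
            mitosis_type=MitosisType.NEGATIVE_MITOSIS,
            noise_sd=cfg.noise_sd,
            background_level=cfg.background_level,
            seed=int(well_rng.integers(0, 2**31 - 1)),
        )
        emit_image(well_id, 0, spec, IntensityClass.NEGATIVE.value, "")
        well_idx += 1

    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(path: str | Path) -> tuple[pd.DataFrame, list[WellRecord]]:
    """Read a manifest and assemble :class:`WellRecord` objects."""
    path = Path(path)
    manifest = pd.read_csv(path, keep_default_na=False)
    wells: list[WellRecord] = []
    for well_id, group in manifest.groupby("well_id", sort=False):
        group = group.sort_values("image_index")
        intensity = IntensityClass.from_label(group["intensity_label"].iloc[0])
        raw_pattern = str(group["pattern_label"].iloc[0])
        pattern = StainingPattern.from_label(raw_pattern) if raw_pattern else None
        wells.append(
            WellRecord(
                well_id=str(well_id),
                images=[str(path.parent / p) for p in group["image_path"]],
                intensity_label=intensity,
                pattern_label=pattern,
            )
        )
    return manifest, wells
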