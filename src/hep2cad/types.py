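"""Core domain types shared across the pipeline.

The vocabulary follows standard ANA/IIF reporting practice: a serum is
read on a HEp-2 substrate well, triaged into one of three fluorescence
intensity classes, and — when non-negative — assigned one of seven nuclear
staining patterns. Mitotic cells carry their own two-way phenotype
(fluorescent chromosome mass vs fluorescent cell body) and act both as a
well quality-control signal and as an auxiliary classification cue.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StainingPattern",
    "IntensityClass",
    "MitosisType",
    "PATTERNS",
    "INTENSITIES",
    "MITOSIS_TYPES",
    "CellRegion",
    "PatternScores",
    "WellRecord",
    "ImageReport",
    "WellReport",
]


class StainingPattern(str, enum.Enum):
    """The seven nuclear staining patterns recognised by the pipeline."""

    HOMOGENEOUS = "homogeneous"
    FINE_SPECKLED = "fine_speckled"
    COARSE_SPECKLED = "coarse_speckled"
    NUCLEOLAR = "nucleolar"
    CENTROMERE = "centromere"
    NUCLEAR_DOTS = "nuclear_dots"
    NUCLEAR_PORE_COMPLEX = "nuclear_pore_complex"

    def __str__(self) -> str:  # manifests serialize the bare value
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "StainingPattern":
        try:
            return cls(label)
        except ValueError:
            raise ValueError(
                f"unknown staining pattern {label!r}; expected one of "
                f"{[p.value for p in cls]}"
            ) from None


class IntensityClass(str, enum.Enum):
    """Three-way fluorescence intensity call for a well or image."""

    NEGATIVE = "negative"
    INTERMEDIATE = "intermediate"
    POSITIVE = "positive"

    def __str__(self) -> str:
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "IntensityClass":
        try:
            return cls(label)
        except ValueError:
            raise ValueError(
                f"unknown intensity class {label!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


class MitosisType(str, enum.Enum):
    """Fluorescence phenotype of a mitotic cell.

    ``NEGATIVE_MITOSIS``: fluorescent cell body, dark collapsed-chromosome
    mass in the middle of the cell. ``POSITIVE_MITOSIS``: the opposite.
    """

    POSITIVE_MITOSIS = "positive_mitosis"
    NEGATIVE_MITOSIS = "negative_mitosis"

    def __str__(self) -> str:
        return self.value

    @classmethod
    def from_label(cls, label: str) -> "MitosisType":
        try:
            return cls(label)
        except ValueError:
            raise ValueError(
                f"unknown mitosis type {label!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


#: Canonical orderings used everywhere scores or labels are vectorised.
PATTERNS: tuple[StainingPattern, ...] = tuple(StainingPattern)
INTENSITIES: tuple[IntensityClass, ...] = tuple(IntensityClass)
MITOSIS_TYPES: tuple[MitosisType, ...] = tuple(MitosisType)


@dataclass
class CellRegion:
    """One segmented (or ground-truth) cell.

    ``mask`` is a full-frame boolean raster; ``bbox`` is 0-based,
    half-open ``(row0, col0, row1, col1)``; ``contour`` is the closed,
    ordered list of 8-connected boundary pixels as ``(row, col)`` pairs.
    """

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    centroid: tuple[float, float]
    contour: np.ndarray
    area: int
    # ground-truth annotations (populated by the simulator)
    pattern: StainingPattern | None = None
    mitosis: MitosisType | None = None

    @property
    def is_mitotic(self) -> bool:
        return self.mitosis is not None

    def local_mask(self) -> np.ndarray:
        r0, c0, r1, c1 = self.bbox
        return self.mask[r0:r1, c0:c1]

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValueError("CellRegion area must be positive")


@dataclass(frozen=True)
class PatternScores:
    """The nine fusion inputs for one cell.

    Seven one-vs-all pattern similarity scores (in canonical pattern
    order) followed by two mitosis scores ``(positive_mitosis,
    negative_mitosis)``. Scores are memberships in [0, 1] and need not
    sum to one.
    """

    pattern_scores: tuple[float, ...]
    mitosis_scores: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.pattern_scores) != len(PATTERNS):
            raise ValueError(
                f"expected {len(PATTERNS)} pattern scores, got "
                f"{len(self.pattern_scores)}"
            )
        if len(self.mitosis_scores) != 2:
            raise ValueError("expected 2 mitosis scores")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.pattern_scores + tuple(self.mitosis_scores))


@dataclass
class WellRecord:
    """One serum's images plus optional reference labels.

    Negative wells carry exactly one image, non-negative wells three.
    """

    well_id: str
    images: list[str]
    intensity_label: IntensityClass | None = None
    pattern_label: StainingPattern | None = None
    reader_id: str | None = None

    def __post_init__(self) -> None:
        if self.intensity_label == IntensityClass.NEGATIVE:
            if len(self.images) != 1:
                raise ValueError(
                    f"negative well {self.well_id!r} must have exactly 1 "
                    f"image, got {len(self.images)}"
                )
            if self.pattern_label is not None:
                raise ValueError(
                    f"negative well {self.well_id!r} cannot carry a pattern "
                    "label"
                )
        elif self.intensity_label is not None and len(self.images) != 3:
            raise ValueError(
                f"non-negative well {self.well_id!r} must have exactly 3 "
                f"images, got {len(self.images)}"
            )


@dataclass
class ImageReport:
    """Per-image CAD output."""

    intensity: IntensityClass
    pattern: StainingPattern | None
    has_mitosis: bool
    n_cells: int
    per_cell_scores: list[PatternScores] = field(default_factory=list)
    per_cell_patterns: list[StainingPattern] = field(default_factory=list)
    unanalyzable: bool = False

    def __post_init__(self) -> None:
        if self.intensity == IntensityClass.NEGATIVE and self.pattern is not None:
            raise ValueError("negative image cannot carry a pattern call")


@dataclass
class WellReport:
    """Per-well CAD output, aggregated over the well's images."""

    well_id: str
    intensity: IntensityClass
    pattern: StainingPattern | None
    discarded: bool
    discard_reason: str | None
    image_reports: list[ImageReport] = field(default_factory=list)
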