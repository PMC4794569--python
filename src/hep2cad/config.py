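"""Run configuration: every tunable knob of the pipeline with its default.

A :class:`RunConfig` is fully serializable to/from YAML so that a run's
effective configuration can be echoed next to its outputs and replayed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "SimulatorConfig",
    "SegmentationConfig",
    "ClassifierConfig",
    "EvaluationConfig",
    "RunConfig",
]


@dataclass
class SimulatorConfig:
    """Parameters of the synthetic HEp-2 well generator.

    Brightness amplitudes are 8-bit gray levels applied to the green
    (FITC) channel; the three intensity classes scale a cell's unit
    texture by ``amplitude[class]``, so for a fixed seed mean brightness
    is strictly monotone negative < intermediate < positive.
    """

    width: int = 320
    height: int = 320
    n_interphase: int = 8
    n_mitotic: int = 1
    cell_radius_min: int = 14
    cell_radius_max: int = 20
    background_level: float = 8.0
    noise_sd: float = 4.0
    # per-intensity-class peak amplitude (gray levels)
    amplitude_negative: float = 36.0
    amplitude_intermediate: float = 95.0
    amplitude_positive: float = 185.0
    #: upper bound on the interior mean of a negative cell (gray levels)
    negative_ceiling: float = 45.0
    #: fraction of the green signal bled into red and blue channels
    channel_bleed: float = 0.05
    #: rejection-sampling attempts per cell before declaring the frame full
    max_placement_attempts: int = 200
    #: dim-to-bright contrast used inside textured patterns (base level as a
    #: fraction of the peak amplitude)
    texture_base_fraction: float = 0.25
    #: fraction of negative wells in a generated dataset
    negative_fraction: float = 0.10
    #: every positive image contains at least one mitotic cell by default,
    #: so the well-discard rule is exercised deliberately
    guarantee_mitosis: bool = True
    image_format: str = "png"
    jpeg_quality: int = 95


@dataclass
class SegmentationConfig:
    """Classical Otsu + watershed segmentation parameters."""

    smoothing_sigma: float = 2.0
    min_area: int = 200
    drop_border: bool = True
    opening_radius: int = 2
    #: minimum separation (px) between watershed seed peaks
    peak_min_distance: int = 16


@dataclass
class ClassifierConfig:
    """Hyperparameters of the four classifier stages."""

    seed: int = 0
    # intensity cascade (two margin classifiers)
    intensity_c_grid: tuple[float, ...] = (0.1, 1.0, 10.0)
    intensity_cv_folds: int = 3
    # seven one-vs-all pattern classifiers
    pattern_c_grid: tuple[float, ...] = (1.0, 10.0)
    pattern_cv_folds: int = 3
    pattern_kernel: str = "rbf"
    #: optional per-class boolean feature masks (pattern value -> mask)
    pattern_feature_masks: dict[str, list[bool]] = field(default_factory=dict)
    #: cap on training cells per pattern for the one-vs-all stage
    max_cells_per_pattern: int = 600
    # two mitosis feed-forward networks
    mitosis_hidden_width: int = 16
    mitosis_max_iter: int = 400
    # K-NN fusion
    fusion_k_grid: tuple[int, ...] = (3, 5, 7, 9)
    fusion_k: int | None = None  # set to override cross-validated selection
    fusion_cv_folds: int = 3
    #: threshold on the max mitosis score for per-image mitosis presence
    mitosis_threshold: float = 0.5
    #: optional rejection floor on the fused confidence ("other" call);
    #: disabled by default
    other_confidence_floor: float | None = None


@dataclass
class EvaluationConfig:
    """Rounding and policy conventions for the statistics reports."""

    kappa_decimals: int = 2
    concordance_percent_decimals: int = 0
    mac_percent_decimals: int = 1
    #: reader+CAD second-reader policy: never | always | confidence
    cad_policy: str = "confidence"
    cad_confidence_threshold: float = 0.5


@dataclass
class RunConfig:
    """Top-level configuration: one seed, one knob set per stage."""

    seed: int = 0
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        kwargs: dict[str, Any] = {}
        sections = {
            "simulator": SimulatorConfig,
            "segmentation": SegmentationConfig,
            "classifier": ClassifierConfig,
            "evaluation": EvaluationConfig,
        }
        for key, value in d.items():
            if key in sections:
                section_cls = sections[key]
                section = section_cls(**value)
                # YAML round-trips tuples as lists; restore declared types
                for f in dataclasses.fields(section_cls):
                    v = getattr(section, f.name)
                    if isinstance(v, list) and "tuple" in str(f.type):
                        setattr(section, f.name, tuple(v))
                kwargs[key] = section
            elif key == "seed":
                kwargs[key] = int(value)
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = RunConfig.from_dict(self.to_dict())
        cfg.seed = seed
        cfg.classifier.seed = seed
        return cfg
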