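"""End-to-end orchestration: dataset -> trained bundle -> well reports.

Training consumes a simulated (or otherwise manifest-described) dataset:
each image is segmented, the detected regions are matched one-to-one
against the ground-truth sidecars, and matched regions inherit the truth
annotations (well pattern for interphase cells, mitosis phenotype for
mitotic figures). This trains the classifiers on the same region
distribution they will see at inference time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classification import (
    ModelBundle,
    _score_cells_batch,
    classify_well,
    image_summary_features,
    train_fusion,
    train_intensity_classifier,
    train_mitosis_classifiers,
    train_pattern_classifiers,
)
from .config import RunConfig
from .features import FEATURE_NAMES, extract_cell_features
from .segmentation import segment_cells
from .simulate import load_manifest, load_sidecar
from .types import IntensityClass, StainingPattern, WellRecord, WellReport

__all__ = [
    "TrainingData",
    "collect_training_data",
    "train_bundle",
    "classify_dataset",
    "well_reports_frame",
]


@dataclass
class TrainingData:
    """Feature matrices and labels harvested from a labelled dataset."""

    cell_features: np.ndarray  # interphase cells of non-negative images
    cell_patterns: list[str]
    mitosis_features: np.ndarray  # all matched cells of non-negative images
    mitosis_labels: list[str]  # pattern value or 'interphase'
    image_summaries: np.ndarray
    image_intensities: list[str]
    cell_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def collect_training_data(
    dataset_dir: str | Path, config: RunConfig | None = None
) -> TrainingData:
    """Segment every manifest image and harvest labelled feature vectors."""
    cfg = config or RunConfig()
    dataset_dir = Path(dataset_dir)
    manifest, _ = load_manifest(dataset_dir / "manifest.csv")

    cell_rows: list[np.ndarray] = []
    cell_patterns: list[str] = []
    mito_rows: list[np.ndarray] = []
    mito_labels: list[str] = []
    summaries: list[np.ndarray] = []
    intensities: list[str] = []
    table_rows: list[dict] = []

    for _, row in manifest.iterrows():
        image_path = dataset_dir / row["image_path"]
        image = iio.imread(image_path)
        truth = load_sidecar(Path(str(image_path) + ".truth.json"))
        regions = segment_cells(image, cfg.segmentation)
        vectors = [extract_cell_features(image, r) for r in regions]
        summaries.append(image_summary_features(image, vectors))
        intensities.append(str(row["intensity_label"]))

        if str(row["intensity_label"]) == IntensityClass.NEGATIVE.value:
            continue
        pattern_label = str(row["pattern_label"])
        # transfer truth annotations by majority ownership of the predicted
        # mask: a positive mitosis often segments as its chromosome mass
        # alone, which an IoU criterion would reject
        for pred_i, (region, fv) in enumerate(zip(regions, vectors)):
            overlaps = [int((region.mask & t.mask).sum()) for t in truth]
            if not overlaps or max(overlaps) < 0.5 * region.area:
                continue
            truth_cell = truth[int(np.argmax(overlaps))]
            if truth_cell.mitosis is None:
                cell_rows.append(fv.values)
                cell_patterns.append(pattern_label)
                mito_rows.append(fv.values)
                mito_labels.append("interphase")
            else:
                mito_rows.append(fv.values)
                mito_labels.append(truth_cell.mitosis.value)
            table_rows.append(
                {
                    "well_id": row["well_id"],
                    "image": row["image_path"],
                    "region_id": pred_i,
                    "label": pattern_label if truth_cell.mitosis is None else truth_cell.mitosis.value,
                }
            )

    return TrainingData(
        cell_features=np.vstack(cell_rows) if cell_rows else np.empty((0, len(FEATURE_NAMES))),
        cell_patterns=cell_patterns,
        mitosis_features=np.vstack(mito_rows) if mito_rows else np.empty((0, len(FEATURE_NAMES))),
        mitosis_labels=mito_labels,
        image_summaries=np.vstack(summaries),
        image_intensities=intensities,
        cell_table=pd.DataFrame(table_rows),
    )


def train_bundle(
    dataset_dir: str | Path, config: RunConfig | None = None
) -> tuple[ModelBundle, dict]:
    """Train every stage on one labelled dataset; returns (bundle, log)."""
    cfg = config or RunConfig()
    data = collect_training_data(dataset_dir, cfg)
    log: dict = {"n_pattern_cells": len(data.cell_patterns)}

    intensity = train_intensity_classifier(
        data.image_summaries, data.image_intensities, cfg.classifier
    )
    log["intensity_cv"] = intensity.cv_log

    pattern_models = train_pattern_classifiers(
        data.cell_features, data.cell_patterns, cfg.classifier
    )
    log["pattern_cv_mac"] = {
        m.pattern.value: m.cv_mac for m in pattern_models
    }

    mitosis_models = train_mitosis_classifiers(
        data.mitosis_features, data.mitosis_labels, cfg.classifier
    )

    bundle = ModelBundle(
        intensity_model=intensity,
        pattern_models=pattern_models,
        mitosis_models=mitosis_models,
        fusion_model=None,  # type: ignore[arg-type]  # fitted just below
        config=cfg.classifier,
        segmentation_config=cfg.segmentation,
        metadata={"seed": cfg.seed},
    )
    fusion_scores = _score_cells_batch(data.cell_features, bundle)
    fusion, fusion_log = train_fusion(fusion_scores, data.cell_patterns, cfg.classifier)
    bundle.fusion_model = fusion
    log["fusion"] = fusion_log
    return bundle, log


def classify_dataset(
    dataset_dir: str | Path, bundle: ModelBundle
) -> list[WellReport]:
    """Classify every well of a manifest-described dataset."""
    _, wells = load_manifest(Path(dataset_dir) / "manifest.csv")
    return [classify_well(w, bundle) for w in wells]


def well_reports_frame(reports: Sequence[WellReport]) -> pd.DataFrame:
    """Flat CSV-ready summary: well_id, intensity, pattern, discarded."""
    return pd.DataFrame(
        [
            {
                "well_id": r.well_id,
                "intensity": r.intensity.value,
                "pattern": r.pattern.value if r.pattern else "",
                "discarded": r.discarded,
            }
            for r in reports
        ]
    )
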