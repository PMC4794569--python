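"""CSV/JSON plumbing: label files, feature tables, well reports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES, FeatureVector
from .pipeline import well_reports_frame
from .types import WellReport

__all__ = [
    "write_feature_table",
    "read_labels",
    "write_labels",
    "write_well_reports",
]


def write_feature_table(
    path: str | Path,
    rows: Sequence[tuple[str, str, int, FeatureVector]],
) -> pd.DataFrame:
    """One row per cell: well_id, image, region_id, then the 108 columns."""
    records = []
    for well_id, image, region_id, fv in rows:
        rec = {"well_id": well_id, "image": image, "region_id": region_id}
        rec.update(dict(zip(FEATURE_NAMES, np.asarray(fv.values, dtype=float))))
        records.append(rec)
    frame = pd.DataFrame(records, columns=["well_id", "image", "region_id", *FEATURE_NAMES])
    frame.to_csv(path, index=False)
    return frame


def read_labels(path: str | Path) -> pd.DataFrame:
    """Label CSV: columns well_id, label[, reader_id]."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"well_id", "label"} - set(frame.columns)
    if missing:
        raise ValueError(f"label file {path!s} lacks columns: {sorted(missing)}")
    return frame


def write_labels(path: str | Path, frame: pd.DataFrame) -> None:
    frame.to_csv(path, index=False)


def write_well_reports(reports: Sequence[WellReport], out_dir: str | Path) -> Path:
    """Write one JSON per well plus a flat CSV summary; returns the CSV path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for r in reports:
        payload = {
            "well_id": r.well_id,
            "intensity": r.intensity.value,
            "pattern": r.pattern.value if r.pattern else None,
            "discarded": r.discarded,
            "discard_reason": r.discard_reason,
            "images": [
                {
                    "intensity": ir.intensity.value,
                    "pattern": ir.pattern.value if ir.pattern else None,
                    "has_mitosis": ir.has_mitosis,
                    "n_cells": ir.n_cells,
                    "unanalyzable": ir.unanalyzable,
                }
                for ir in r.image_reports
            ],
        }
        (out_dir / f"{r.well_id}.json").write_text(json.dumps(payload, indent=1))
    csv_path = out_dir / "well_reports.csv"
    well_reports_frame(reports).to_csv(csv_path, index=False)
    return csv_path
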