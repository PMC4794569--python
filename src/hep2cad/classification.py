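"""The CAD decision stages.

The workflow mirrors clinical IIF reading. An image is first triaged by
fluorescence intensity (negative / intermediate / positive) with a
two-stage cascade of margin classifiers; pattern analysis runs only on
non-negative images. Every segmented cell is then pushed through seven
one-vs-all pattern classifiers and two small feed-forward mitosis
networks, and the resulting nine membership scores are fused by a K-NN
classifier in score space into the cell's final pattern call. Image- and
well-level calls are majorities over cells and images respectively, and
a non-negative well with no detected mitotic cell is flagged as discarded
(mitoses certify that the well was prepared correctly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .config import ClassifierConfig, SegmentationConfig
from .features import FEATURE_NAMES, FeatureVector, extract_cell_features
from .segmentation import segment_cells
from .types import (
    INTENSITIES,
    MITOSIS_TYPES,
    PATTERNS,
    CellRegion,
    ImageReport,
    IntensityClass,
    MitosisType,
    PatternScores,
    StainingPattern,
    WellRecord,
    WellReport,
)

__all__ = [
    "ModelBundle",
    "image_summary_features",
    "train_intensity_classifier",
    "train_pattern_classifiers",
    "train_mitosis_classifiers",
    "train_fusion",
    "score_cell",
    "classify_image",
    "classify_well",
    "KnnFusion",
]

BUNDLE_SCHEMA_VERSION = 1

#: length of the per-image summary vector used by the intensity cascade
N_GLOBAL_STATS = 6


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def _tuned_svc(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: Sequence[float],
    folds: int,
    seed: int,
    kernel: str = "rbf",
) -> tuple[Pipeline, float, float]:
    """Fit a standardized SVC, choosing C by cross-validated mean class accuracy."""
    best = None
    classes, counts = np.unique(y, return_counts=True)
    n_folds = int(min(folds, counts.min()))
    for c in c_grid:
        if n_folds >= 2:
            cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
            scores = []
            for train_idx, test_idx in cv.split(X, y):
                model = make_pipeline(
                    StandardScaler(), SVC(C=c, kernel=kernel, gamma="scale")
                )
                model.fit(X[train_idx], y[train_idx])
                scores.append(
                    balanced_accuracy_score(y[test_idx], model.predict(X[test_idx]))
                )
            cv_mac = float(np.mean(scores))
        else:
            cv_mac = 0.0
        if best is None or cv_mac > best[1]:
            best = (c, cv_mac)
    c_best, cv_mac = best
    model = make_pipeline(StandardScaler(), SVC(C=c_best, kernel=kernel, gamma="scale"))
    model.fit(X, y)
    return model, float(c_best), cv_mac


class _ConstantBinary:
    """Degenerate stage predicting one class; keeps the cascade total."""

    def __init__(self, label: int):
        self.label = label

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), self.label, dtype=int)

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return np.full(len(X), np.inf if self.label == 1 else -np.inf)


@dataclass
class IntensityCascade:
    """negative-vs-rest, then intermediate-vs-positive."""

    negative_stage: Pipeline | _ConstantBinary
    grade_stage: Pipeline | _ConstantBinary
    cv_log: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> list[IntensityClass]:
        X = np.asarray(X, dtype=float)
        is_nonneg = self.negative_stage.predict(X)
        is_positive = self.grade_stage.predict(X)
        out = []
        for nn, pos in zip(is_nonneg, is_positive):
            if nn == 0:
                out.append(IntensityClass.NEGATIVE)
            elif pos == 1:
                out.append(IntensityClass.POSITIVE)
            else:
                out.append(IntensityClass.INTERMEDIATE)
        return out


def image_summary_features(
    image: np.ndarray, cell_vectors: Sequence[FeatureVector]
) -> np.ndarray:
    """Per-image summary: mean and sd of the cell descriptors plus global
    green-channel statistics (mean, sd, 10th/50th/90th percentiles, and the
    fraction of pixels above 30 gray levels)."""
    green = (image[..., 1] if image.ndim == 3 else image).astype(float)
    global_stats = np.array(
        [
            green.mean(),
            green.std(),
            np.percentile(green, 10),
            np.percentile(green, 50),
            np.percentile(green, 90),
            float((green > 30).mean()),
        ]
    )
    if cell_vectors:
        stack = np.vstack([fv.values for fv in cell_vectors])
        mean = stack.mean(axis=0)
        sd = stack.std(axis=0)
    else:
        mean = np.zeros(len(FEATURE_NAMES))
        sd = np.zeros(len(FEATURE_NAMES))
    return np.concatenate([mean, sd, global_stats])


def train_intensity_classifier(
    summaries: np.ndarray,
    labels: Sequence[IntensityClass | str],
    config: ClassifierConfig | None = None,
) -> IntensityCascade:
    """Train the two-stage intensity cascade on per-image summary vectors."""
    cfg = config or ClassifierConfig()
    X = np.asarray(summaries, dtype=float)
    y = [IntensityClass.from_label(str(l)) for l in labels]
    present = sorted({v.value for v in y})
    if len(present) < 2:
        raise ValueError(
            f"intensity training requires at least 2 classes, got {present}"
        )
    cv_log: dict = {}
    y_nonneg = np.array([0 if v is IntensityClass.NEGATIVE else 1 for v in y])
    if len(np.unique(y_nonneg)) == 2:
        neg_stage, c, mac = _tuned_svc(
            X, y_nonneg, cfg.intensity_c_grid, cfg.intensity_cv_folds, cfg.seed
        )
        cv_log["negative_stage"] = {"C": c, "cv_mac": mac}
    else:
        neg_stage = _ConstantBinary(int(y_nonneg[0]))
    nonneg_idx = np.flatnonzero(y_nonneg == 1)
    y_pos = np.array(
        [1 if y[i] is IntensityClass.POSITIVE else 0 for i in nonneg_idx]
    )
    if len(nonneg_idx) and len(np.unique(y_pos)) == 2:
        grade_stage, c, mac = _tuned_svc(
            X[nonneg_idx], y_pos, cfg.intensity_c_grid, cfg.intensity_cv_folds, cfg.seed
        )
        cv_log["grade_stage"] = {"C": c, "cv_mac": mac}
    else:
        grade_stage = _ConstantBinary(int(y_pos[0]) if len(y_pos) else 0)
    return IntensityCascade(negative_stage=neg_stage, grade_stage=grade_stage, cv_log=cv_log)


@dataclass
class PatternClassifier:
    """One one-vs-all pattern model emitting a [0, 1] membership score."""

    pattern: StainingPattern
    model: Pipeline
    feature_mask: np.ndarray | None = None
    cv_mac: float = 0.0

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.feature_mask is not None:
            X = X[:, self.feature_mask]
        return _sigmoid(self.model.decision_function(X))


def _validate_feature_matrix(features: Sequence[FeatureVector] | np.ndarray) -> np.ndarray:
    if isinstance(features, np.ndarray):
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
    else:
        X = np.vstack([fv.values for fv in features])
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError(
            f"feature schema mismatch: expected {len(FEATURE_NAMES)} columns, "
            f"got {X.shape[1]}"
        )
    return X


def train_pattern_classifiers(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[StainingPattern | str],
    config: ClassifierConfig | None = None,
) -> list[PatternClassifier]:
    """Train the seven one-vs-all pattern classifiers, in canonical order.

    Each model standardizes features on its own training split and is
    tuned by cross-validated mean class accuracy over the configured C
    grid. An optional per-pattern boolean feature mask restricts the
    descriptor columns a given classifier sees.
    """
    cfg = config or ClassifierConfig()
    X = _validate_feature_matrix(features)
    y = np.array([StainingPattern.from_label(str(l)).value for l in labels])
    missing = [p.value for p in PATTERNS if p.value not in set(y)]
    if missing:
        raise ValueError(f"training data lacks pattern classes: {missing}")
    if cfg.max_cells_per_pattern:
        rng = np.random.default_rng(cfg.seed)
        keep: list[np.ndarray] = []
        for p in PATTERNS:
            idx = np.flatnonzero(y == p.value)
            if len(idx) > cfg.max_cells_per_pattern:
                idx = rng.choice(idx, size=cfg.max_cells_per_pattern, replace=False)
                idx.sort()
            keep.append(idx)
        sel = np.concatenate(keep)
        X, y = X[sel], y[sel]
    models: list[PatternClassifier] = []
    for p in PATTERNS:
        mask = None
        if p.value in cfg.pattern_feature_masks:
            mask = np.asarray(cfg.pattern_feature_masks[p.value], dtype=bool)
        Xp = X[:, mask] if mask is not None else X
        y_bin = (y == p.value).astype(int)
        model, _, cv_mac = _tuned_svc(
            Xp, y_bin, cfg.pattern_c_grid, cfg.pattern_cv_folds, cfg.seed,
            kernel=cfg.pattern_kernel,
        )
        models.append(
            PatternClassifier(pattern=p, model=model, feature_mask=mask, cv_mac=cv_mac)
        )
    return models


@dataclass
class MitosisClassifier:
    """One small feed-forward network scoring one mitosis phenotype vs rest."""

    mitosis_type: MitosisType
    model: Pipeline

    def score(self, X: np.ndarray) -> np.ndarray:
        proba = self.model.predict_proba(np.asarray(X, dtype=float))
        positive_col = list(self.model.classes_).index(1)
        return proba[:, positive_col]


def train_mitosis_classifiers(
    features: Sequence[FeatureVector] | np.ndarray,
    labels: Sequence[str],
    config: ClassifierConfig | None = None,
) -> list[MitosisClassifier]:
    """Train the two mitosis networks (positive-vs-rest, negative-vs-rest).

    ``labels`` take values 'positive_mitosis', 'negative_mitosis' or
    'interphase'. Each network has one hidden layer and is seeded for
    deterministic initialization.
    """
    cfg = config or ClassifierConfig()
    X = _validate_feature_matrix(features)
    y = np.array([str(l) for l in labels])
    valid = {m.value for m in MITOSIS_TYPES} | {"interphase"}
    unknown = sorted(set(y) - valid)
    if unknown:
        raise ValueError(f"unknown mitosis training labels: {unknown}")
    missing = sorted(valid - set(y))
    if missing:
        raise ValueError(f"mitosis training data lacks categories: {missing}")
    models = []
    for m in MITOSIS_TYPES:
        y_bin = (y == m.value).astype(int)
        net = make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(cfg.mitosis_hidden_width,),
                max_iter=cfg.mitosis_max_iter,
                random_state=cfg.seed,
            ),
        )
        net.fit(X, y_bin)
        models.append(MitosisClassifier(mitosis_type=m, model=net))
    return models


class KnnFusion:
    """K-nearest-neighbour fusion in the 9-dimensional score space.

    Euclidean metric; the predicted pattern is the majority label among
    the K nearest training scores, with ties broken first by the smallest
    summed neighbour distance and then by canonical pattern order.
    """

    def __init__(self, k: int):
        if k < 1 or k % 2 == 0:
            raise ValueError("K must be a positive odd integer")
        self.k = k
        self._X: np.ndarray | None = None
        self._y: np.ndarray | None = None

    def fit(self, scores: np.ndarray, labels: Sequence[str]) -> "KnnFusion":
        X = np.asarray(scores, dtype=float)
        if X.ndim != 2 or X.shape[1] != 9:
            raise ValueError(
                f"fusion consumes exactly 9 score inputs per cell, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        if len(X) < self.k:
            raise ValueError(
                f"fusion requires at least K={self.k} training points, got {len(X)}"
            )
        self._X = X
        self._y = np.array([StainingPattern.from_label(str(l)).value for l in labels])
        return self

    def predict(self, scores: np.ndarray) -> list[StainingPattern]:
        if self._X is None:
            raise RuntimeError("fusion model is not fitted")
        Q = np.asarray(scores, dtype=float)
        if Q.ndim == 1:
            Q = Q[None, :]
        if Q.shape[1] != 9:
            raise ValueError(
                f"fusion consumes exactly 9 score inputs per cell, got {Q.shape[1]}"
            )
        out: list[StainingPattern] = []
        order_rank = {p.value: i for i, p in enumerate(PATTERNS)}
        for q in Q:
            d = np.linalg.norm(self._X - q, axis=1)
            nn = np.argsort(d, kind="stable")[: self.k]
            votes: dict[str, int] = {}
            dist_sum: dict[str, float] = {}
            for i in nn:
                lab = self._y[i]
                votes[lab] = votes.get(lab, 0) + 1
                dist_sum[lab] = dist_sum.get(lab, 0.0) + float(d[i])
            best = min(
                votes,
                key=lambda lab: (-votes[lab], dist_sum[lab], order_rank[lab]),
            )
            out.append(StainingPattern(best))
        return out


def train_fusion(
    scores: Sequence[PatternScores] | np.ndarray,
    labels: Sequence[StainingPattern | str],
    config: ClassifierConfig | None = None,
) -> tuple[KnnFusion, dict]:
    """Fit the fusion K-NN, selecting odd K by cross-validated MAC.

    K is chosen from the configured grid unless ``config.fusion_k`` pins
    it explicitly.
    """
    cfg = config or ClassifierConfig()
    if isinstance(scores, np.ndarray):
        X = np.asarray(scores, dtype=float)
    else:
        X = np.vstack([s.as_array() for s in scores])
    y = np.array([StainingPattern.from_label(str(l)).value for l in labels])
    missing = [p.value for p in PATTERNS if p.value not in set(y)]
    if missing:
        raise ValueError(f"fusion training data lacks pattern classes: {missing}")
    log: dict = {}
    if cfg.fusion_k is not None:
        k_best = cfg.fusion_k
    else:
        counts = np.bincount(np.unique(y, return_inverse=True)[1])
        n_folds = int(min(cfg.fusion_cv_folds, counts.min()))
        k_best, best_mac = cfg.fusion_k_grid[0], -1.0
        for k in cfg.fusion_k_grid:
            if k > len(X) or n_folds < 2:
                continue
            cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=cfg.seed)
            macs = []
            for tr, te in cv.split(X, y):
                if k > len(tr):
                    continue
                model = KnnFusion(k).fit(X[tr], y[tr])
                pred = [p.value for p in model.predict(X[te])]
                macs.append(balanced_accuracy_score(y[te], pred))
            if macs and np.mean(macs) > best_mac:
                best_mac = float(np.mean(macs))
                k_best = k
        log["cv_mac"] = best_mac if best_mac >= 0 else None
    log["k"] = k_best
    return KnnFusion(k_best).fit(X, y), log


@dataclass
class ModelBundle:
    """All trained stages plus the metadata to reproduce them."""

    intensity_model: IntensityCascade
    pattern_models: list[PatternClassifier]
    mitosis_models: list[MitosisClassifier]
    fusion_model: KnnFusion
    config: ClassifierConfig
    segmentation_config: SegmentationConfig
    metadata: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "schema_version": BUNDLE_SCHEMA_VERSION,
            "feature_names": list(FEATURE_NAMES),
            "patterns": [p.value for p in PATTERNS],
            "fusion_k": self.fusion_model.k,
            **self.metadata,
        }
        (directory / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
        joblib.dump(
            {
                "intensity_model": self.intensity_model,
                "pattern_models": self.pattern_models,
                "mitosis_models": self.mitosis_models,
                "fusion_X": self.fusion_model._X,
                "fusion_y": self.fusion_model._y,
                "config": self.config,
                "segmentation_config": self.segmentation_config,
            },
            directory / "models.joblib",
        )

    @classmethod
    def load(cls, directory: str | Path) -> "ModelBundle":
        directory = Path(directory)
        meta = json.loads((directory / "metadata.json").read_text())
        if meta.get("schema_version") != BUNDLE_SCHEMA_VERSION:
            raise ValueError(
                f"bundle schema version {meta.get('schema_version')!r} is not "
                f"supported (expected {BUNDLE_SCHEMA_VERSION})"
            )
        blob = joblib.load(directory / "models.joblib")
        fusion = KnnFusion(meta["fusion_k"])
        fusion._X = blob["fusion_X"]
        fusion._y = blob["fusion_y"]
        return cls(
            intensity_model=blob["intensity_model"],
            pattern_models=blob["pattern_models"],
            mitosis_models=blob["mitosis_models"],
            fusion_model=fusion,
            config=blob["config"],
            segmentation_config=blob["segmentation_config"],
            metadata={
                k: v
                for k, v in meta.items()
                if k not in {"schema_version", "feature_names", "patterns", "fusion_k"}
            },
        )


def score_cell(
    features: FeatureVector | np.ndarray, bundle: ModelBundle
) -> PatternScores:
    """Compute the nine fusion inputs for one cell."""
    X = _validate_feature_matrix(
        features if isinstance(features, np.ndarray) else [features]
    )
    pattern_scores = tuple(float(m.score(X)[0]) for m in bundle.pattern_models)
    mitosis_scores = tuple(float(m.score(X)[0]) for m in bundle.mitosis_models)
    return PatternScores(pattern_scores=pattern_scores, mitosis_scores=mitosis_scores)


def _score_cells_batch(X: np.ndarray, bundle: ModelBundle) -> np.ndarray:
    cols = [m.score(X) for m in bundle.pattern_models]
    cols += [m.score(X) for m in bundle.mitosis_models]
    return np.column_stack(cols)


def _majority_pattern(
    cell_patterns: list[StainingPattern], score_matrix: np.ndarray
) -> StainingPattern:
    """Majority vote; ties broken by highest mean fused-class score."""
    values = [p.value for p in cell_patterns]
    counts = {v: values.count(v) for v in set(values)}
    top = max(counts.values())
    tied = [v for v, c in counts.items() if c == top]
    if len(tied) == 1:
        return StainingPattern(tied[0])
    means = {}
    for v in tied:
        col = [p.value for p in PATTERNS].index(v)
        means[v] = float(score_matrix[:, col].mean())
    rank = {p.value: i for i, p in enumerate(PATTERNS)}
    return StainingPattern(max(tied, key=lambda v: (means[v], -rank[v])))


def classify_image(
    image: np.ndarray,
    bundle: ModelBundle,
    regions: list[CellRegion] | None = None,
) -> ImageReport:
    """Classify one frame: intensity triage, then per-cell pattern fusion.

    No pattern or mitosis model is evaluated for an image triaged
    negative. Cells whose maximal mitosis score exceeds the configured
    threshold set the image's mitosis flag and abstain from the pattern
    vote (unless every cell is flagged).
    """
    if regions is None:
        regions = segment_cells(image, bundle.segmentation_config)
    vectors = [extract_cell_features(image, r) for r in regions]
    summary = image_summary_features(image, vectors)
    intensity = bundle.intensity_model.predict(summary[None, :])[0]
    if intensity is IntensityClass.NEGATIVE:
        return ImageReport(
            intensity=intensity,
            pattern=None,
            has_mitosis=False,
            n_cells=len(regions),
        )
    if not regions:
        return ImageReport(
            intensity=intensity,
            pattern=None,
            has_mitosis=False,
            n_cells=0,
            unanalyzable=True,
        )
    X = np.vstack([fv.values for fv in vectors])
    score_matrix = _score_cells_batch(X, bundle)
    per_cell_scores = [
        PatternScores(
            pattern_scores=tuple(row[:7].tolist()),
            mitosis_scores=(float(row[7]), float(row[8])),
        )
        for row in score_matrix
    ]
    fused = bundle.fusion_model.predict(score_matrix)
    mitotic_flags = score_matrix[:, 7:9].max(axis=1) > bundle.config.mitosis_threshold
    has_mitosis = bool(mitotic_flags.any())
    vote_idx = np.flatnonzero(~mitotic_flags)
    if vote_idx.size == 0:
        vote_idx = np.arange(len(fused))
    pattern = _majority_pattern(
        [fused[i] for i in vote_idx], score_matrix[vote_idx]
    )
    if bundle.config.other_confidence_floor is not None:
        col = [p.value for p in PATTERNS].index(pattern.value)
        if score_matrix[vote_idx, col].max() < bundle.config.other_confidence_floor:
            pattern = None  # rejection: confidence below the "other" floor
    return ImageReport(
        intensity=intensity,
        pattern=pattern,
        has_mitosis=has_mitosis,
        n_cells=len(regions),
        per_cell_scores=per_cell_scores,
        per_cell_patterns=list(fused),
    )


def _load_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    try:
        return iio.imread(path)
    except FileNotFoundError:
        raise FileNotFoundError(f"cannot read image file {path!s}") from None


def classify_well(well: WellRecord, bundle: ModelBundle) -> WellReport:
    """Aggregate image calls into a well call.

    Intensity is the majority over images (ties resolved toward the more
    positive class); the pattern is the majority over non-negative image
    patterns; the well is discarded when non-negative but no image shows
    a mitotic cell.
    """
    if len(well.images) not in (1, 3):
        raise ValueError(
            f"well {well.well_id!r} must have 1 or 3 images, got {len(well.images)}"
        )
    reports = [classify_image(_load_image(p), bundle) for p in well.images]

    intensity_rank = {c: i for i, c in enumerate(INTENSITIES)}
    votes: dict[IntensityClass, int] = {}
    for r in reports:
        votes[r.intensity] = votes.get(r.intensity, 0) + 1
    top = max(votes.values())
    intensity = max(
        (c for c, v in votes.items() if v == top), key=lambda c: intensity_rank[c]
    )

    pattern: StainingPattern | None = None
    pattern_votes: dict[str, int] = {}
    for r in reports:
        if r.intensity is not IntensityClass.NEGATIVE and r.pattern is not None:
            pattern_votes[r.pattern.value] = pattern_votes.get(r.pattern.value, 0) + 1
    if intensity is not IntensityClass.NEGATIVE and pattern_votes:
        top = max(pattern_votes.values())
        rank = {p.value: i for i, p in enumerate(PATTERNS)}
        pattern = StainingPattern(
            min(
                (v for v, c in pattern_votes.items() if c == top),
                key=lambda v: rank[v],
            )
        )

    discarded = False
    reason = None
    if intensity is not IntensityClass.NEGATIVE and not any(
        r.has_mitosis for r in reports
    ):
        discarded = True
        reason = "no mitosis detected"
    return WellReport(
        well_id=well.well_id,
        intensity=intensity,
        pattern=pattern,
        discarded=discarded,
        discard_reason=reason,
        image_reports=reports,
    )
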