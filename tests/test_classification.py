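"""Classifier-stage tests: training contracts, fusion K-NN against a
brute-force oracle, triage gating, well aggregation and bundle round-trip."""

import numpy as np
import pytest
from sklearn.neighbors import KNeighborsClassifier

import hep2cad as h
from hep2cad.classification import (
    KnnFusion,
    ModelBundle,
    _score_cells_batch,
    classify_image,
    classify_well,
    image_summary_features,
    score_cell,
)
from hep2cad.config import ClassifierConfig, RunConfig
from hep2cad.features import FEATURE_NAMES
from hep2cad.pipeline import collect_training_data
from hep2cad.simulate import ImageSpec, load_manifest
from hep2cad.types import IntensityClass, PatternScores, StainingPattern, WellRecord


@pytest.fixture(scope="module")
def training_data(tiny_dataset_dir):
    return collect_training_data(tiny_dataset_dir, RunConfig())


def _cell_vector(pattern, seed):
    patch, mask = h.generate_cell(pattern, "positive", 16, seed=seed)
    frame = np.zeros((*patch.shape, 3), dtype=np.uint8)
    frame[..., 1] = np.clip(np.rint(patch), 0, 255)
    from hep2cad.segmentation import region_from_mask

    return h.extract_cell_features(frame, region_from_mask(mask))


class TestIntensityCascade:
    def test_single_class_training_rejected(self, training_data):
        X = training_data.image_summaries[:6]
        with pytest.raises(ValueError, match="at least 2 classes"):
            h.train_intensity_classifier(X, ["positive"] * 6)

    def test_predictions_use_closed_vocabulary(self, tiny_bundle, training_data):
        preds = tiny_bundle.intensity_model.predict(training_data.image_summaries)
        assert all(isinstance(p, IntensityClass) for p in preds)

    def test_heldout_intensity_accuracy_beats_chance(self, tiny_bundle, tiny_test_dataset_dir):
        data = collect_training_data(tiny_test_dataset_dir, RunConfig())
        preds = tiny_bundle.intensity_model.predict(data.image_summaries)
        acc = np.mean([p.value == t for p, t in zip(preds, data.image_intensities)])
        assert acc > 1 / 3


class TestPatternClassifiers:
    def test_seven_models_in_canonical_order(self, tiny_bundle):
        assert [m.pattern for m in tiny_bundle.pattern_models] == list(h.PATTERNS)

    def test_missing_class_error_lists_labels(self, training_data):
        keep = [
            i
            for i, lab in enumerate(training_data.cell_patterns)
            if lab != "centromere"
        ]
        with pytest.raises(ValueError, match="centromere"):
            h.train_pattern_classifiers(
                training_data.cell_features[keep],
                [training_data.cell_patterns[i] for i in keep],
            )

    def test_scores_bounded_for_arbitrary_vectors(self, tiny_bundle, rng):
        X = rng.normal(0, 50, size=(20, len(FEATURE_NAMES)))
        for m in tiny_bundle.pattern_models:
            s = m.score(X)
            assert np.all((0 <= s) & (s <= 1))

    def test_own_class_scores_above_median_of_rest(self, tiny_bundle, training_data):
        model = tiny_bundle.pattern_models[0]  # homogeneous
        y = np.array(training_data.cell_patterns)
        X = training_data.cell_features
        own = model.score(X[y == "homogeneous"]).mean()
        rest = np.median(model.score(X[y != "homogeneous"]))
        assert own > rest


class TestMitosisClassifiers:
    def test_two_models_returned(self, tiny_bundle):
        assert [m.mitosis_type for m in tiny_bundle.mitosis_models] == list(h.MITOSIS_TYPES)

    def test_missing_category_rejected(self, training_data):
        y = ["interphase"] * len(training_data.mitosis_labels)
        with pytest.raises(ValueError, match="lacks categories"):
            h.train_mitosis_classifiers(training_data.mitosis_features, y)

    def test_positive_mitosis_scores_higher_than_interphase(self, tiny_bundle):
        """Averaged over 20 seeded scenes, a segmented positive mitosis
        outranks a segmented interphase cell on the positive-mitosis model."""
        pos_model = tiny_bundle.mitosis_models[0]

        def scene_score(n_interphase, n_mitotic, seed):
            spec = ImageSpec(
                width=128, height=128, n_interphase=n_interphase,
                n_mitotic=n_mitotic, seed=seed,
                mitosis_type=h.MitosisType.POSITIVE_MITOSIS,
            )
            img = h.generate_image(spec)
            regions = h.segment_cells(img.pixels)
            if not regions:
                return None
            fv = h.extract_cell_features(img.pixels, regions[0])
            return pos_model.score(fv.values[None, :])[0]

        mito = [scene_score(0, 1, 200 + s) for s in range(20)]
        inter = [scene_score(1, 0, 300 + s) for s in range(20)]
        mito = [s for s in mito if s is not None]
        inter = [s for s in inter if s is not None]
        assert np.mean(mito) > np.mean(inter)

    def test_deterministic_given_seed(self, training_data):
        cfg = ClassifierConfig(seed=5, mitosis_max_iter=50)
        a = h.train_mitosis_classifiers(
            training_data.mitosis_features, training_data.mitosis_labels, cfg
        )
        b = h.train_mitosis_classifiers(
            training_data.mitosis_features, training_data.mitosis_labels, cfg
        )
        X = training_data.mitosis_features[:10]
        np.testing.assert_array_equal(a[0].score(X), b[0].score(X))


class TestScoreCell:
    def test_nine_finite_scores(self, tiny_bundle):
        scores = score_cell(_cell_vector("nucleolar", 44), tiny_bundle)
        arr = scores.as_array()
        assert arr.shape == (9,)
        assert np.all(np.isfinite(arr))

    def test_wrong_length_is_schema_error(self, tiny_bundle):
        with pytest.raises(ValueError, match="schema"):
            score_cell(np.zeros(107), tiny_bundle)

    def test_deterministic(self, tiny_bundle):
        fv = _cell_vector("centromere", 45)
        a = score_cell(fv, tiny_bundle).as_array()
        b = score_cell(fv, tiny_bundle).as_array()
        np.testing.assert_array_equal(a, b)


class TestKnnFusion:
    def test_exact_match_returns_training_label(self, rng):
        X = rng.random((30, 9))
        y = [h.PATTERNS[i % 7].value for i in range(30)]
        model = KnnFusion(1).fit(X, y)
        assert model.predict(X[4])[0].value == y[4]

    def test_agrees_with_brute_force_scan(self, rng):
        # two classes with odd K: majority votes can never tie, so any
        # disagreement would be a genuine nearest-neighbour defect
        X = rng.random((50, 9))
        y = np.array([h.PATTERNS[i % 2].value for i in range(50)])
        queries = rng.random((25, 9))
        for k in (3, 5):
            ours = [p.value for p in KnnFusion(k).fit(X, y).predict(queries)]
            ref = KNeighborsClassifier(n_neighbors=k).fit(X, y).predict(queries)
            assert ours == list(ref)

    def test_tie_broken_by_pattern_order(self):
        # two training points equidistant from the query, different labels
        X = np.zeros((3, 9))
        X[0, 0] = 1.0
        X[1, 0] = -1.0
        X[2, 1] = 5.0  # far away
        y = ["nucleolar", "homogeneous", "centromere"]
        pred = KnnFusion(3).fit(X, y).predict(np.zeros(9))
        # votes: nucleolar 1, homogeneous 1, centromere 1 at distance 5 —
        # summed distance equal for the two near ones; homogeneous is
        # earlier in canonical pattern order
        assert pred[0] is StainingPattern.HOMOGENEOUS

    def test_fewer_points_than_k_rejected(self, rng):
        with pytest.raises(ValueError, match="at least K"):
            KnnFusion(9).fit(rng.random((4, 9)), ["homogeneous"] * 4)

    def test_fusion_consumes_exactly_nine_inputs(self, rng):
        with pytest.raises(ValueError, match="9 score"):
            KnnFusion(1).fit(rng.random((10, 8)), ["homogeneous"] * 10)
        model = KnnFusion(1).fit(rng.random((10, 9)), ["homogeneous"] * 10)
        with pytest.raises(ValueError, match="9 score"):
            model.predict(rng.random((2, 10)))

    def test_train_fusion_selects_odd_k(self, training_data, tiny_bundle):
        scores = _score_cells_batch(training_data.cell_features, tiny_bundle)
        model, log = h.train_fusion(scores, training_data.cell_patterns)
        assert model.k in (3, 5, 7, 9)
        assert log["k"] == model.k


class TestClassifyImage:
    def test_negative_image_skips_pattern_models(self, tiny_bundle, monkeypatch):
        img = h.generate_image(
            ImageSpec(seed=61, intensity=IntensityClass.NEGATIVE)
        )
        calls = []
        for m in tiny_bundle.pattern_models:
            original = m.score
            monkeypatch.setattr(
                m, "score", lambda X, _o=original: calls.append(1) or _o(X)
            )
        report = classify_image(img.pixels, tiny_bundle)
        if report.intensity is IntensityClass.NEGATIVE:
            assert report.pattern is None
            assert calls == []

    def test_positive_image_gets_pattern_from_vocabulary(self, tiny_bundle):
        img = h.generate_image(
            ImageSpec(seed=62, pattern=StainingPattern.CENTROMERE)
        )
        report = classify_image(img.pixels, tiny_bundle)
        if report.intensity is not IntensityClass.NEGATIVE:
            assert report.pattern in set(h.PATTERNS)

    def test_reports_deterministic(self, tiny_bundle):
        img = h.generate_image(ImageSpec(seed=63))
        a = classify_image(img.pixels, tiny_bundle)
        b = classify_image(img.pixels, tiny_bundle)
        assert (a.intensity, a.pattern, a.has_mitosis, a.n_cells) == (
            b.intensity,
            b.pattern,
            b.has_mitosis,
            b.n_cells,
        )


class TestClassifyWell:
    def test_no_mitosis_well_discarded_with_reason(self, tiny_bundle, tmp_path):
        import imageio.v3 as iio

        paths = []
        for i in range(3):
            spec = ImageSpec(seed=70 + i, n_mitotic=0,
                             pattern=StainingPattern.HOMOGENEOUS)
            img = h.generate_image(spec)
            p = tmp_path / f"img{i}.png"
            iio.imwrite(p, img.pixels)
            paths.append(str(p))
        well = WellRecord(well_id="Wx", images=paths)
        report = classify_well(well, tiny_bundle)
        assert report.discarded
        assert report.discard_reason == "no mitosis detected"

    def test_negative_well_not_discarded(self, tiny_bundle, tmp_path):
        import imageio.v3 as iio

        spec = ImageSpec(seed=75, intensity=IntensityClass.NEGATIVE)
        img = h.generate_image(spec)
        p = tmp_path / "neg.png"
        iio.imwrite(p, img.pixels)
        report = classify_well(WellRecord(well_id="Wn", images=[str(p)]), tiny_bundle)
        if report.intensity is IntensityClass.NEGATIVE:
            assert report.pattern is None
            assert not report.discarded

    def test_unanimous_images_set_well_pattern(self, tiny_bundle, tiny_test_dataset_dir):
        _, wells = load_manifest(tiny_test_dataset_dir / "manifest.csv")
        well = next(w for w in wells if w.pattern_label is not None)
        report = classify_well(well, tiny_bundle)
        votes = {
            r.pattern for r in report.image_reports
            if r.pattern is not None
        }
        if len(votes) == 1:
            assert report.pattern in votes

    def test_unreadable_image_error_names_path(self, tiny_bundle):
        well = WellRecord(well_id="Wz", images=["/nonexistent/img.png"] * 3)
        with pytest.raises(FileNotFoundError, match="/nonexistent/img.png"):
            classify_well(well, tiny_bundle)


class TestBundleRoundTrip:
    def test_save_load_identical_predictions(self, tiny_bundle, tmp_path, rng):
        tiny_bundle.save(tmp_path / "bundle")
        loaded = ModelBundle.load(tmp_path / "bundle")
        probes = [
            _cell_vector(p.value, 500 + i) for i, p in enumerate(h.PATTERNS[:3])
        ]
        for fv in probes:
            a = score_cell(fv, tiny_bundle).as_array()
            b = score_cell(fv, loaded).as_array()
            np.testing.assert_array_equal(a, b)
            pa = tiny_bundle.fusion_model.predict(a)
            pb = loaded.fusion_model.predict(b)
            assert pa == pb

    def test_schema_version_checked(self, tiny_bundle, tmp_path):
        import json

        d = tmp_path / "bundle2"
        tiny_bundle.save(d)
        meta = json.loads((d / "metadata.json").read_text())
        meta["schema_version"] = 99
        (d / "metadata.json").write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="schema version"):
            ModelBundle.load(d)


def test_pattern_scores_requires_nine_values():
    with pytest.raises(ValueError):
        PatternScores(pattern_scores=(0.1,) * 6, mitosis_scores=(0.5, 0.5))
    with pytest.raises(ValueError):
        PatternScores(pattern_scores=(0.1,) * 7, mitosis_scores=(0.5,))
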