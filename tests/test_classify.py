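"""Training-set curation, forest classification, confidence scoring,
hierarchical evaluation, importance, and feature reduction."""

import numpy as np
import pandas as pd
import pytest

from hcfm.classify import (
    ForestModel,
    PredictionResult,
    TrainingSet,
    aggregate_hierarchical,
    confidence_curve,
    cross_validated_predictions,
    curate_training_set,
    evaluate_hierarchical,
    feature_importance,
    feature_reduction_curve,
    filter_by_confidence,
    predict_with_confidence,
    train_classifier,
)
from hcfm.features import CATALOG_VERSION
from hcfm.io import LabelTable
from hcfm.taxonomy import TaxonomyTree


def _feature_frame(object_ids, rng, n_features=6):
    cols = {f"f{i}": rng.normal(size=len(object_ids)) for i in range(n_features)}
    return pd.DataFrame(
        {"sample": "s", "field_row": 0, "field_col": 0, "object_id": object_ids, **cols}
    )


def _labels(counts):
    records, oid = [], 0
    for leaf, n in counts.items():
        for _ in range(n):
            oid += 1
            records.append((oid, "root", f"g_{leaf}", f"f_{leaf}", leaf))
    return LabelTable.from_records(records)


def _gaussian_training_set(n_classes=3, n_per_class=60, sep=6.0, seed=0, n_features=10):
    rng = np.random.default_rng(seed)
    X, y, paths = [], [], []
    for k in range(n_classes):
        mu = np.zeros(n_features)
        mu[k % n_features] = sep
        X.append(rng.normal(mu, 1.0, size=(n_per_class, n_features)))
        y += [f"leaf{k}"] * n_per_class
        paths.append((f"top{k % 2}", f"mid{k}", f"sub{k}", f"leaf{k}"))
    return TrainingSet(
        X=np.vstack(X), y=np.array(y), tree=TaxonomyTree.from_paths(paths)
    )


class TestCuration:
    def test_strictly_more_than_30_rule(self):
        rng = np.random.default_rng(16)
        labels = _labels({"A": 40, "B": 30, "C": 31})
        feats = _feature_frame(labels.frame["object_id"], rng)
        train = curate_training_set(labels, feats)
        kept = set(np.unique(train.y))
        assert kept == {"A", "C"}
        assert len(train.y) == 71

    def test_all_above_threshold_is_identity(self):
        rng = np.random.default_rng(17)
        labels = _labels({"A": 35, "B": 31})
        feats = _feature_frame(labels.frame["object_id"], rng)
        train = curate_training_set(labels, feats)
        assert len(train.y) == 66

    def test_nothing_surviving_raises_with_counts(self):
        rng = np.random.default_rng(18)
        labels = _labels({"A": 30, "B": 30})
        feats = _feature_frame(labels.frame["object_id"], rng)
        with pytest.raises(ValueError, match="counts"):
            curate_training_set(labels, feats)


class TestForest:
    def test_separable_classes_have_high_oob_accuracy(self):
        train = _gaussian_training_set(n_classes=2, n_per_class=100, sep=8.0, seed=1)
        model = train_classifier(train, seed=0, n_trees=100, oob_score=True)
        assert model.estimator.oob_score_ >= 0.95

    def test_same_seed_gives_identical_predictions(self):
        train = _gaussian_training_set(seed=2)
        rng = np.random.default_rng(19)
        probe = rng.normal(size=(20, train.X.shape[1]))
        p1 = predict_with_confidence(train_classifier(train, seed=5, n_trees=50), probe)
        p2 = predict_with_confidence(train_classifier(train, seed=5, n_trees=50), probe)
        assert [a.predicted for a in p1] == [a.predicted for a in p2]
        np.testing.assert_array_equal(
            np.stack([a.probabilities for a in p1]),
            np.stack([a.probabilities for a in p2]),
        )

    def test_permuted_labels_give_chance_accuracy(self):
        train = _gaussian_training_set(n_classes=4, n_per_class=50, sep=8.0, seed=3)
        rng = np.random.default_rng(20)
        train_null = TrainingSet(
            X=train.X, y=rng.permutation(train.y), tree=train.tree
        )
        y_pred = cross_validated_predictions(train_null, folds=5, seed=0, n_trees=50)
        acc = float((y_pred == train_null.y).mean())
        # chance is 0.25; binomial 3-sigma band at n=200
        assert abs(acc - 0.25) < 3 * np.sqrt(0.25 * 0.75 / len(train_null.y))

    def test_single_class_rejected(self):
        train = _gaussian_training_set(n_classes=1)
        with pytest.raises(ValueError):
            train_classifier(train, seed=0, n_trees=10)

    def test_probabilities_sum_to_one(self):
        train = _gaussian_training_set(seed=4)
        model = train_classifier(train, seed=0, n_trees=50)
        preds = predict_with_confidence(model, train.X[:25])
        for p in preds:
            assert p.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
            assert 0.0 <= p.confidence <= 1.0


class TestConfidence:
    def _result(self, probs):
        probs = np.asarray(probs, dtype=float)
        order = np.argsort(-probs, kind="stable")
        second = probs[order[1]] if len(probs) > 1 else 0.0
        return PredictionResult(
            probabilities=probs,
            classes=np.array([f"c{i}" for i in range(len(probs))]),
            predicted=f"c{order[0]}",
            confidence=float(probs[order[0]] - second),
        )

    def test_definition_arithmetic(self):
        r = self._result([0.7, 0.2, 0.1])
        assert r.predicted == "c0"
        assert r.confidence == pytest.approx(0.5)

    def test_tie_breaks_to_lower_index_with_zero_confidence(self):
        r = self._result([0.5, 0.5])
        assert r.predicted == "c0"
        assert r.confidence == 0.0

    def test_single_class_confidence_is_one(self):
        r = self._result([1.0])
        assert r.confidence == 1.0

    def test_cutoff_zero_retains_all_and_curve_monotone(self):
        train = _gaussian_training_set(n_classes=3, n_per_class=80, sep=2.0, seed=5)
        model = train_classifier(train, seed=0, n_trees=100)
        preds = predict_with_confidence(model, train.X)
        assert len(filter_by_confidence(preds, 0.0)) == len(preds)
        curve = confidence_curve(preds, train.y, cutoffs=[0.0, 0.3, 0.6])
        accs = curve["accuracy"].to_numpy()
        assert np.all(np.diff(accs) >= -0.02)  # non-decreasing up to noise
        assert curve["retained_fraction"].iloc[0] == 1.0


class TestHierarchicalEvaluation:
    TREE = TaxonomyTree.from_paths(
        [("A", "A1", "A11", "x"), ("A", "A1", "A11", "y"), ("B", "B1", "B11", "z")]
    )

    def test_perfect_predictions_are_perfect_at_all_levels(self):
        y = np.array(["x", "y", "z", "x"])
        report = aggregate_hierarchical(y, y, self.TREE)
        assert all(report.accuracy[k] == 1.0 for k in range(1, 5))

    def test_sibling_confusion_correct_at_coarse_level_only(self):
        y_true = np.array(["x", "x", "y", "y"])
        y_pred = np.array(["y", "y", "x", "x"])  # wrong leaf, same level-1..3
        report = aggregate_hierarchical(y_true, y_pred, self.TREE)
        assert report.accuracy[4] == 0.0
        assert report.accuracy[1] == 1.0

    def test_matches_brute_force_aggregation_of_confusion_matrix(self):
        # hand-built 3x3 leaf confusion: rows true x,y,z
        confusion = np.array([[5, 2, 1], [1, 6, 0], [0, 3, 9]])
        leaves = ["x", "y", "z"]
        y_true, y_pred = [], []
        for i, t in enumerate(leaves):
            for j, p in enumerate(leaves):
                y_true += [t] * confusion[i, j]
                y_pred += [p] * confusion[i, j]
        report = aggregate_hierarchical(y_true, y_pred, self.TREE)
        n = confusion.sum()
        # brute force: leaf level = trace / total
        assert report.accuracy[4] == pytest.approx(np.trace(confusion) / n)
        # levels 1-3: x and y collapse, z stays
        merged_correct = (
            confusion[0, :2].sum() + confusion[1, :2].sum() + confusion[2, 2]
        )
        for level in (1, 2, 3):
            assert report.accuracy[level] == pytest.approx(merged_correct / n)
        # per-category recall at leaf level
        for i, leaf in enumerate(leaves):
            assert report.recall[4][leaf] == pytest.approx(
                confusion[i, i] / confusion[i].sum()
            )

    def test_leaf_correct_implies_correct_at_all_levels(self):
        rng = np.random.default_rng(21)
        leaves = np.array(["x", "y", "z"])
        y_true = rng.choice(leaves, size=60)
        y_pred = rng.choice(leaves, size=60)
        report = aggregate_hierarchical(y_true, y_pred, self.TREE)
        assert all(
            report.accuracy[k] >= report.accuracy[4] - 1e-12 for k in (1, 2, 3)
        )

    def test_cv_report_determinism(self):
        train = _gaussian_training_set(seed=6)
        r1 = evaluate_hierarchical(train, folds=4, seed=3, n_trees=30)
        r2 = evaluate_hierarchical(train, folds=4, seed=3, n_trees=30)
        assert r1.accuracy == r2.accuracy
        np.testing.assert_array_equal(r1.y_pred, r2.y_pred)


class TestImportanceAndReduction:
    def test_normalized_importance_has_unit_mean(self):
        train = _gaussian_training_set(seed=7)
        model = train_classifier(train, seed=0, n_trees=50)
        imp = feature_importance(model)
        assert imp.mean() == pytest.approx(1.0)

    def test_signal_feature_outranks_noise(self):
        rng = np.random.default_rng(22)
        n = 200
        signal = np.repeat([0.0, 5.0], n // 2) + rng.normal(0, 0.5, n)
        noise = rng.normal(size=n)
        X = np.column_stack([noise, signal])
        y = np.repeat(["a", "b"], n // 2)
        tree = TaxonomyTree.from_paths([("t", "m", "s", "a"), ("t", "m", "s", "b")])
        model = train_classifier(TrainingSet(X=X, y=y, tree=tree), seed=0, n_trees=100)
        imp = feature_importance(model)
        assert imp[0] < 1.0 < imp[1]

    def test_identical_copies_share_importance(self):
        rng = np.random.default_rng(23)
        base = np.repeat([0.0, 4.0], 100) + rng.normal(0, 0.5, 200)
        X = np.column_stack([base] * 4)
        y = np.repeat(["a", "b"], 100)
        tree = TaxonomyTree.from_paths([("t", "m", "s", "a"), ("t", "m", "s", "b")])
        model = train_classifier(TrainingSet(X=X, y=y, tree=tree), seed=0, n_trees=200)
        imp = feature_importance(model)
        np.testing.assert_allclose(imp, 1.0, atol=0.15)

    def test_full_k_equals_plain_cv_and_k1_below_k2(self):
        # two informative features, the rest noise
        rng = np.random.default_rng(24)
        n = 240
        y = np.repeat(["a", "b", "c"], n // 3)
        f1 = (y == "b") * 4.0 + rng.normal(0, 1, n)
        f2 = (y == "c") * 4.0 + rng.normal(0, 1, n)
        X = np.column_stack([f1, f2] + [rng.normal(size=n) for _ in range(4)])
        tree = TaxonomyTree.from_paths(
            [("t", "m", "s", leaf) for leaf in ("a", "b", "c")]
        )
        train = TrainingSet(X=X, y=y, tree=tree)
        curve = feature_reduction_curve(train, k_grid=[1, 2, 6], folds=4, seed=0, n_trees=60)
        acc = dict(zip(curve["k"], curve["accuracy"]))
        y_pred = cross_validated_predictions(train, folds=4, seed=0, n_trees=60)
        assert acc[6] == pytest.approx(float((y_pred == y).mean()))
        assert acc[1] < acc[2]

    def test_k_out_of_range_rejected(self):
        train = _gaussian_training_set(seed=8)
        with pytest.raises(ValueError):
            feature_reduction_curve(train, k_grid=[999], folds=3, seed=0, n_trees=10)


class TestModelIO:
    def test_save_load_round_trip(self, tmp_path):
        train = _gaussian_training_set(seed=9)
        model = train_classifier(train, seed=7, n_trees=20)
        model.save(tmp_path / "model.joblib")
        back = ForestModel.load(tmp_path / "model.joblib")
        assert back.catalog_version == CATALOG_VERSION
        assert back.seed == 7
        rng = np.random.default_rng(25)
        probe = rng.normal(size=(10, train.X.shape[1]))
        assert [p.predicted for p in predict_with_confidence(back, probe)] == [
            p.predicted for p in predict_with_confidence(model, probe)
        ]
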