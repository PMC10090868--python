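"""Validation protocol, classifier backends and the metric formulas."""

import numpy as np
import pandas as pd
import pytest

from ppgsleep.evaluate import (ConfusionMatrix, ModelSpec, compute_metrics,
                               kfold_select, prepare_matrix, run_generic_eval,
                               split_70_30, subject_specific_eval, train)
from ppgsleep.features import FEATURE_NAMES
from ppgsleep.selection import select_features
from ppgsleep.stages import SLEEP, WAKE


class TestSplit7030:
    def test_split_proportions(self):
        y = ["A"] * 500 + ["B"] * 500
        splits = split_70_30(y, repeats=5, seed=0)
        assert len(splits) == 5
        for tr, te in splits:
            assert len(tr) == 700 and len(te) == 300
            assert set(tr) & set(te) == set()

    def test_same_seed_same_splits(self):
        y = ["A"] * 60 + ["B"] * 40
        a = split_70_30(y, seed=3)
        b = split_70_30(y, seed=3)
        for (t1, e1), (t2, e2) in zip(a, b):
            assert np.array_equal(t1, t2) and np.array_equal(e1, e2)

    def test_repeats_are_distinct(self):
        y = ["A"] * 60 + ["B"] * 40
        splits = split_70_30(y, repeats=5, seed=1)
        trains = [tuple(sorted(tr)) for tr, _ in splits]
        assert len(set(trains)) == 5


class TestKfoldSelect:
    def test_singleton_grid_returned(self, rng):
        X = rng.normal(size=(60, 3))
        y = np.array(["A", "B"] * 30)
        spec = ModelSpec(kind="svm_poly")
        assert kfold_select(X, y, [spec]) is spec

    def test_separable_candidate_beats_degenerate_one(self, rng):
        y = np.array(["A"] * 50 + ["B"] * 50)
        X = np.column_stack([(y == "B") * 10.0 + rng.normal(0, 0.1, 100)])
        good = ModelSpec(kind="svm_poly")
        # a 1-NN forced onto one neighbour of shuffled labels can't do better
        weak = ModelSpec(kind="subspace_knn", K=99, k_grid=(99,), n_learners=3)
        assert kfold_select(X, y, [good, weak], k=5).kind == "svm_poly"

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            kfold_select(np.zeros((10, 1)), np.zeros(10), [])


class TestTrain:
    @pytest.mark.parametrize("kind", ["subspace_knn", "svm_poly", "bagged_rf"])
    def test_separable_two_class_reaches_full_accuracy(self, rng, kind):
        y = np.array([WAKE] * 100 + [SLEEP] * 100)
        X = np.column_stack([
            (y == SLEEP) * 8.0 + rng.normal(0, 0.2, 200),
            rng.normal(size=200),
        ])
        model = train(ModelSpec(kind=kind, seed=0), X[::2], y[::2])
        assert np.mean(model.predict(X[1::2]) == y[1::2]) == 1.0

    @pytest.mark.parametrize("kind", ["subspace_knn", "svm_poly", "bagged_rf"])
    def test_same_seed_identical_predictions(self, rng, kind):
        X = rng.normal(size=(150, 8))
        y = rng.choice([WAKE, SLEEP], size=150)
        a = train(ModelSpec(kind=kind, seed=42), X, y).predict(X)
        b = train(ModelSpec(kind=kind, seed=42), X, y).predict(X)
        assert np.array_equal(a, b)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            train(ModelSpec(), rng.normal(size=(10, 2)), np.zeros(9))


class TestComputeMetrics:
    def test_binary_formulas_from_counts(self):
        # TP=50 TN=30 FP=10 FN=10 for the positive class
        cm = ConfusionMatrix(classes=("neg", "pos"),
                             counts=np.array([[30, 10], [10, 50]]))
        m = compute_metrics(cm)["per_class"]["pos"]
        assert m["accuracy"] == pytest.approx(80.0)
        assert m["sensitivity"] == pytest.approx(83.33, abs=0.01)
        assert m["specificity"] == pytest.approx(75.0)

    def test_fscore_is_harmonic_mean_of_sens_and_spec(self):
        # sens 80, spec 60 -> 2*80*60/140 = 68.57
        cm = ConfusionMatrix(classes=("neg", "pos"),
                             counts=np.array([[60, 40], [20, 80]]))
        m = compute_metrics(cm)["per_class"]["pos"]
        assert m["sensitivity"] == pytest.approx(80.0)
        assert m["specificity"] == pytest.approx(60.0)
        assert m["fscore"] == pytest.approx(68.57, abs=0.01)

    def test_standard_f1_available_behind_flag(self):
        cm = ConfusionMatrix(classes=("neg", "pos"),
                             counts=np.array([[60, 40], [20, 80]]))
        m = compute_metrics(cm, fscore="f1")["per_class"]["pos"]
        prec, sens = 100 * 80 / 120, 80.0
        assert m["fscore"] == pytest.approx(2 * prec * sens / (prec + sens))

    def test_perfect_predictions_hit_100(self):
        cm = ConfusionMatrix(classes=("a", "b", "c"),
                             counts=np.diag([10, 20, 30]))
        m = compute_metrics(cm)
        assert m["overall_accuracy"] == 100.0
        assert m["sensitivity"] == 100.0

    def test_row_sums_equal_per_class_test_counts(self):
        y_true = np.array(["a"] * 7 + ["b"] * 5)
        y_pred = np.array(["a"] * 4 + ["b"] * 3 + ["b"] * 4 + ["a"])
        cm = ConfusionMatrix.from_predictions(y_true, y_pred, ("a", "b"))
        assert cm.counts.sum() == 12
        assert list(cm.counts.sum(axis=1)) == [7, 5]


class TestEndToEnd:
    def test_separable_corpus_accuracy_bounds(self, corpus_features):
        # separability is by construction of the synthetic presets; this
        # checks the assembled pipeline, not any clinical performance
        two = run_generic_eval(corpus_features, "two",
                               ModelSpec(kind="svm_poly"), repeats=2, seed=7)
        four = run_generic_eval(corpus_features, "four",
                                ModelSpec(kind="svm_poly"), repeats=2, seed=7)
        assert two.aggregate()["overall_accuracy"]["mean"] > 85.0
        assert four.aggregate()["overall_accuracy"]["mean"] > 60.0
        assert 0.5 < four.aggregate()["auc"]["mean"] <= 1.0

    def test_subject_specific_eval_reports_each_subject(self, corpus_features):
        reports = subject_specific_eval(corpus_features, "two",
                                        ModelSpec(kind="bagged_rf", n_trees=30),
                                        seed=1)
        assert set(reports) == set(corpus_features["subject_id"].unique())
        for rep in reports.values():
            acc = rep.aggregate()["overall_accuracy"]["mean"]
            assert acc > 50.0  # above two-class chance within each subject

    def test_no_leakage_from_test_partition(self, corpus_features):
        """Corrupting test labels must not change training artifacts."""
        df, y = prepare_matrix(corpus_features, "four")
        X = df[list(FEATURE_NAMES)]
        tr, te = split_70_30(y, repeats=1, seed=0)[0]
        rep_clean = select_features(X.iloc[tr], y[tr], "four")
        y_bad = y.copy()
        y_bad[te] = np.roll(y[te], 1)  # corrupt only the test partition
        rep_dirty = select_features(X.iloc[tr], y_bad[tr], "four")
        assert rep_clean.selected_features == rep_dirty.selected_features
        pd.testing.assert_frame_equal(rep_clean.table, rep_dirty.table)

    def test_eval_report_serialises(self, corpus_features, tmp_path):
        rep = run_generic_eval(corpus_features, "two",
                               ModelSpec(kind="svm_poly"), repeats=2, seed=2)
        path = tmp_path / "report.json"
        rep.to_json(path)
        import json
        payload = json.loads(path.read_text())
        assert payload["scheme"] == "two"
        assert len(payload["splits"]) == 2
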