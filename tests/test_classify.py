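"""LOOCV logistic regression and the confusion/kappa/ROC metric suite."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import binom, rankdata
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from bqfmri.classify import (CohortFeatures, auc_trapezoidal, binary_report,
                             confusion_matrix, evaluate_features,
                             f1_from_precision_recall, loocv_folds,
                             loocv_predict, multiclass_report)


def make_clusters(rng, n_per_class=6, n_features=8, sep=8.0, labels=("A", "B", "C")):
    """Well-separated Gaussian clusters, one per label."""
    xs, ys = [], []
    for i, lab in enumerate(labels):
        xs.append(rng.standard_normal((n_per_class, n_features)) + sep * i)
        ys += [lab] * n_per_class
    return CohortFeatures(matrix=np.vstack(xs), labels=ys)


def mann_whitney_auc(y, scores, positive):
    """Brute-force AUC oracle: normalized rank-sum with mid-rank ties."""
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray([t == positive for t in y])
    r = rankdata(scores)
    n1, n0 = pos.sum(), (~pos).sum()
    return (r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = ["A", "B", "C", "A"]
        assert np.array_equal(confusion_matrix(y, y, ["A", "B", "C"]),
                              np.diag([2, 1, 1]))

    def test_hand_example(self):
        out = confusion_matrix(["A", "A", "B"], ["B", "A", "B"], ["A", "B"])
        assert out.tolist() == [[1, 1], [0, 1]]

    def test_total_equals_sample_count(self, rng):
        y_true = rng.choice(list("ABC"), 50)
        y_pred = rng.choice(list("ABC"), 50)
        assert confusion_matrix(y_true, y_pred, ["A", "B", "C"]).sum() == 50

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside class order"):
            confusion_matrix(["A"], ["D"], ["A", "B"])


class TestMulticlassReport:
    def test_perfect_diagonal(self):
        rep = multiclass_report(np.diag([10, 12, 11]))
        assert rep["accuracy"] == 1.0 and rep["kappa"] == 1.0

    def test_hand_computed_kappa(self):
        # p_o = 0.7, p_e = 0.5 -> kappa = 0.4
        rep = multiclass_report(np.array([[20, 5], [10, 15]]))
        assert rep["accuracy"] == pytest.approx(0.7)
        assert rep["kappa"] == pytest.approx(0.4)

    def test_single_predicted_class_has_zero_kappa(self):
        rep = multiclass_report(np.array([[12, 0], [30, 0]]))
        assert rep["kappa"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_true_class_reports_missing_ccr(self):
        rep = multiclass_report(np.array([[5, 0], [0, 0]]))
        assert rep["ccr_per_class"][1] is None

    @given(st.lists(st.integers(0, 30), min_size=9, max_size=9))
    @settings(max_examples=50, deadline=None)
    def test_accuracy_is_weighted_mean_of_ccrs(self, counts):
        conf = np.array(counts).reshape(3, 3)
        if conf.sum() == 0 or (conf.sum(axis=1) == 0).any():
            return
        rep = multiclass_report(conf)
        weights = conf.sum(axis=1) / conf.sum()
        assert rep["accuracy"] == pytest.approx(
            float(np.dot(weights, rep["ccr_per_class"])), abs=1e-12)

    def test_kappa_agrees_with_sklearn(self, rng):
        y_true = rng.choice(list("ABC"), 60)
        y_pred = rng.choice(list("ABC"), 60)
        conf = confusion_matrix(y_true, y_pred, ["A", "B", "C"])
        assert multiclass_report(conf)["kappa"] == pytest.approx(
            cohen_kappa_score(y_true, y_pred), abs=1e-12)


class TestBinaryReportAndAuc:
    def test_f1_of_published_precision_recall(self):
        assert round(f1_from_precision_recall(0.89, 0.94), 2) == 0.91

    def test_perfectly_ranked_scores_have_unit_auc(self):
        y = ["neg"] * 5 + ["pos"] * 5
        scores = np.linspace(0, 1, 10)
        assert auc_trapezoidal(y, scores, "pos") == 1.0

    def test_null_scores_have_half_auc(self, rng):
        # scores independent of labels: mean AUC over shuffles ~ 0.5
        y = ["neg"] * 20 + ["pos"] * 20
        aucs = [auc_trapezoidal(y, rng.standard_normal(40), "pos")
                for _ in range(200)]
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.03)

    def test_auc_matches_mann_whitney_oracle_with_ties(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 50))
            y = rng.choice(["a", "b"], n)
            if len(set(y)) < 2:
                continue
            scores = rng.integers(0, 5, n).astype(float)  # heavy ties
            ours = auc_trapezoidal(y, scores, "b")
            assert ours == pytest.approx(mann_whitney_auc(y, scores, "b"), abs=1e-10)
            assert ours == pytest.approx(
                roc_auc_score([t == "b" for t in y], scores), abs=1e-10)

    def test_no_positive_predictions_reports_missing(self):
        y_true = ["pos", "neg", "pos"]
        y_pred = ["neg", "neg", "neg"]
        rep = binary_report(y_true, y_pred, [0.4, 0.3, 0.45], "pos")
        assert rep["precision"] is None and rep["f1"] is None
        assert rep["recall"] == 0.0


class TestLoocv:
    def test_separable_clusters_classified_perfectly(self, rng):
        features = make_clusters(rng)
        y_true, y_pred, scores, order = loocv_predict(features, seed=0)
        assert y_true == y_pred
        assert scores.shape == (18, 3)

    def test_one_fold_and_prediction_per_map(self, rng):
        features = make_clusters(rng, n_per_class=4)
        y_true, y_pred, _, _ = loocv_predict(features, seed=0)
        assert len(y_pred) == 12 and all(p != "" for p in y_pred)
        assert len(loocv_folds(12, features.subject_ids, "map")) == 12

    def test_subject_grouping_holds_out_whole_subjects(self):
        sids = ["s0", "s0", "s1", "s1", "s2", "s2"]
        folds = loocv_folds(6, sids, "subject")
        assert len(folds) == 3
        assert all(len(test) == 2 for _, test in folds)

    def test_permuted_labels_never_beat_chance(self, rng):
        # Under permuted labels LOOCV must show no optimistic leakage: the
        # pooled correct count over 20 replicates stays at or below the
        # upper 95% binomial bound of chance 1/3.  (It routinely falls
        # *below* chance: holding out a map leaves its class as the
        # training minority, the classic pessimistic LOOCV bias, so a
        # two-sided band around 1/3 is not the right null here.)
        features = make_clusters(rng, n_per_class=6, n_features=5)
        n = len(features.labels)
        correct = 0
        for _ in range(20):
            perm = list(rng.permutation(features.labels))
            f = CohortFeatures(matrix=features.matrix, labels=perm)
            y_true, y_pred, _, _ = loocv_predict(f, seed=0)
            correct += sum(t == p for t, p in zip(y_true, y_pred))
        assert correct <= binom.ppf(0.975, 20 * n, 1 / 3)

    def test_pair_task_drops_third_class(self, rng):
        features = make_clusters(rng)
        y_true, y_pred, scores, order = loocv_predict(features, ("A", "C"), seed=0)
        assert set(y_true) == {"A", "C"} and len(y_true) == 12
        assert order == ["A", "C"]

    def test_class_too_small_rejected(self, rng):
        features = CohortFeatures(matrix=rng.standard_normal((5, 3)),
                                  labels=["A", "A", "A", "B", "B"])
        with pytest.raises(ValueError, match=">= 3 maps"):
            loocv_predict(features, seed=0)

    def test_class_absent_from_training_fold_names_fold(self, rng):
        # all maps of class B belong to one subject: holding it out empties B
        features = CohortFeatures(
            matrix=rng.standard_normal((9, 4)),
            labels=["A"] * 6 + ["B"] * 3,
            subject_ids=["a0", "a1", "a2", "a3", "a4", "a5", "b", "b", "b"])
        with pytest.raises(ValueError, match="fold"):
            loocv_predict(features, seed=0, grouping="subject")


class TestEvaluateFeatures:
    def test_full_report_structure(self, rng):
        features = make_clusters(rng, n_per_class=5)
        rep = evaluate_features(features, seed=0)
        assert rep.confusion.sum() == 15
        assert rep.multiclass["accuracy"] == 1.0
        assert set(rep.pairs) == {"A_vs_B", "A_vs_C", "B_vs_C"}
        for pair in rep.pairs.values():
            assert pair["auc"] == 1.0 and pair["f1"] == 1.0
        assert len(rep.fold_predictions) == 15

    def test_report_round_trips_to_json(self, rng, tmp_path):
        rep = evaluate_features(make_clusters(rng, n_per_class=4), seed=0)
        rep.save(tmp_path / "report.json")
        import json
        loaded = json.loads((tmp_path / "report.json").read_text())
        assert loaded["multiclass"]["accuracy"] == rep.multiclass["accuracy"]
        assert (tmp_path / "report.predictions.csv").exists()
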