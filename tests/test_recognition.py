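"""Feature assembly and classifier evaluation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from distractnet.recognition import (
    build_feature_table,
    feature_columns,
    feature_importance,
    select_features,
    train_evaluate,
)
from distractnet.topology import TopologyProfile


def _fake_profile(est, band, value=0.5):
    grid = np.array([0.1, 0.2])
    curves = {f: np.array([value, value]) for f in ("Lg", "Cg", "Eg", "El")}
    auc = {f: value for f in ("Lg", "Cg", "Eg", "El")}
    return TopologyProfile(est, band, grid, curves, auc, strength=value)


def _fake_epoch(state="normal", subject=0, idx=0):
    from distractnet.preprocessing import LabeledEpoch

    return LabeledEpoch(np.zeros((2, 64)), 64.0, state, subject=subject, epoch_index=idx)


class TestBuildFeatureTable:
    def test_full_set_60_columns(self):
        prof = {
            (e, b): _fake_profile(e, b)
            for e in ("SL", "PLV", "COH")
            for b in ("delta", "theta", "alpha", "beta")
        }
        table = build_feature_table([(_fake_epoch(), prof)])
        assert len(feature_columns(table)) == 60

    def test_sl_only_20_columns(self):
        prof = {
            (e, b): _fake_profile(e, b)
            for e in ("SL", "PLV", "COH")
            for b in ("delta", "theta", "alpha", "beta")
        }
        table = build_feature_table([(_fake_epoch(), prof)])
        sub = select_features(table, estimators=["SL"])
        assert len(feature_columns(sub)) == 20

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty cohort"):
            build_feature_table([])

    def test_missing_profile_rejected_naming_epoch(self):
        prof = {("SL", "delta"): _fake_profile("SL", "delta")}
        with pytest.raises(ValueError, match="subject=3"):
            build_feature_table([(_fake_epoch(subject=3), prof)])


class TestTrainEvaluate:
    @pytest.mark.parametrize("clf", ["knn", "rf", "gboost", "svm"])
    def test_separable_classes_perfect_accuracy(self, separable_table, clf):
        report = train_evaluate(separable_table, task="ternary", classifier=clf, seed=0)
        assert report.test_accuracy == 1.0
        assert report.cv_accuracy == 1.0

    def test_binary_relabeling(self, separable_table):
        report = train_evaluate(separable_table, task="binary", classifier="knn", seed=0)
        assert set(report.classes) == {"normal", "distracted"}
        assert report.test_accuracy == 1.0

    def test_permuted_labels_give_chance_accuracy(self, separable_table):
        """Shuffling labels collapses CV accuracy to ~1/3: no leakage through
        the in-fold standardization or the split."""
        accs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            t = separable_table.copy()
            t["state"] = rng.permutation(t["state"].to_numpy())
            rep = train_evaluate(t, task="ternary", classifier="knn", seed=s)
            accs.append(rep.cv_accuracy)
        assert abs(np.mean(accs) - 1.0 / 3.0) < 0.1

    def test_metrics_consistent_with_confusion_matrix(self, separable_table):
        t = separable_table.copy()
        rng = np.random.default_rng(1)
        noise_cols = feature_columns(t)
        t[noise_cols] = t[noise_cols].to_numpy() + rng.normal(0, 25.0, t[noise_cols].shape)
        rep = train_evaluate(t, task="ternary", classifier="knn", seed=1)
        cm = rep.confusion
        acc = np.trace(cm) / cm.sum()
        assert rep.test_accuracy == pytest.approx(acc)
        with np.errstate(invalid="ignore"):
            prec = np.mean(np.where(cm.sum(0) > 0, np.diag(cm) / cm.sum(0), 0.0))
            rec = np.mean(np.where(cm.sum(1) > 0, np.diag(cm) / cm.sum(1), 0.0))
        assert rep.precision == pytest.approx(prec, abs=1e-9)
        assert rep.recall == pytest.approx(rec, abs=1e-9)

    def test_deterministic_given_seed(self, separable_table):
        a = train_evaluate(separable_table, classifier="gboost", seed=5)
        b = train_evaluate(separable_table, classifier="gboost", seed=5)
        assert np.array_equal(a.cv_scores, b.cv_scores)
        assert a.test_accuracy == b.test_accuracy
        assert np.array_equal(a.confusion, b.confusion)

    def test_subject_grouped_split(self, separable_table):
        rep = train_evaluate(separable_table, classifier="knn", seed=0, split="subject")
        assert rep.cv_config["split"] == "subject"
        assert rep.test_accuracy == 1.0

    def test_unknown_task_rejected(self, separable_table):
        with pytest.raises(ValueError, match="task"):
            train_evaluate(separable_table, task="quaternary")

    def test_tiny_class_rejected_with_advice(self, separable_table):
        t = separable_table[separable_table["state"] != "visual"].copy()
        t = pd.concat([t, separable_table[separable_table["state"] == "visual"].head(1)])
        with pytest.raises(ValueError, match="resample"):
            train_evaluate(t, task="ternary")

    def test_confusion_rows_sum_to_class_counts(self, separable_table):
        rep = train_evaluate(separable_table, task="ternary", classifier="knn", seed=0)
        assert rep.confusion.sum() == 9  # test split: 10% of 90, floored at classes
        assert (rep.confusion.sum(axis=1) > 0).all()


class TestFeatureImportance:
    def test_single_informative_feature_dominates(self, separable_table):
        rng = np.random.default_rng(0)
        t = separable_table.copy()
        cols = feature_columns(t)
        t[cols] = rng.normal(0, 1.0, t[cols].shape)  # wipe all signal
        signal_col = "SL_theta_El"
        t[signal_col] = t["state"].map({"normal": 0.0, "cognitive": 5.0, "visual": 10.0})
        rep = train_evaluate(t, task="ternary", classifier="gboost", seed=0)
        imp = feature_importance(rep)
        assert imp.ranking.iloc[0]["feature"] == signal_col
        assert imp.ranking.iloc[0]["importance"] > 0.5

    def test_shares_normalized(self, separable_table):
        rep = train_evaluate(separable_table, task="ternary", classifier="rf", seed=0)
        imp = feature_importance(rep)
        assert imp.ranking["importance"].sum() == pytest.approx(1.0, abs=1e-9)
        assert sum(imp.estimator_share.values()) == pytest.approx(1.0, abs=1e-9)
        assert sum(imp.band_share.values()) == pytest.approx(1.0, abs=1e-9)
        assert set(imp.estimator_share) == {"SL", "PLV", "COH"}

    def test_rejected_for_non_tree_classifier(self, separable_table):
        rep = train_evaluate(separable_table, task="ternary", classifier="svm", seed=0)
        with pytest.raises(ValueError, match="importances"):
            feature_importance(rep)
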