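"""State recognition: feature assembly, classifier training and evaluation.

The feature table carries one row per epoch with up to 60 named features,
``{SL,PLV,COH} x {delta,theta,alpha,beta} x {V,Cg,Lg,Eg,El}`` (column
naming convention ``estimator_band_feature``), plus ``state``, ``subject``
and ``epoch`` metadata columns.

Evaluation protocol: an outer stratified 90/10 split reserves a test set;
stratified 10-fold cross-validation runs on the 90% development split;
the report records both the CV-mean metrics and the held-out-test metrics.
Standardization is fitted inside each training fold (sklearn Pipeline), so
no scaling information leaks across folds.  A subject-grouped split mode
keeps all epochs of a subject on one side of every split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import (
    GroupShuffleSplit,
    StratifiedGroupKFold,
    StratifiedKFold,
    cross_val_score,
    train_test_split,
)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import LabelEncoder, StandardScaler
from sklearn.svm import SVC
from xgboost import XGBClassifier

from distractnet.bands import BAND_ORDER
from distractnet.connectivity import ESTIMATORS
from distractnet.preprocessing import LabeledEpoch
from distractnet.topology import TopologyProfile

CLASSIFIERS: tuple[str, ...] = ("knn", "rf", "gboost", "svm")
TASKS: tuple[str, ...] = ("binary", "ternary")
META_COLUMNS: tuple[str, ...] = ("state", "subject", "epoch")


def build_feature_table(
    profiles: Sequence[tuple[LabeledEpoch, Mapping[tuple[str, str], TopologyProfile]]],
    estimators: Sequence[str] = ESTIMATORS,
    bands: Sequence[str] = BAND_ORDER,
) -> pd.DataFrame:
    """Assemble the per-epoch feature table from topology profiles.

    ``profiles`` pairs each epoch with its (estimator, band) -> profile map;
    a missing profile is an error naming the epoch.
    """
    if not profiles:
        raise ValueError("empty cohort: no epochs to build features from")
    rows = []
    for ep, prof_map in profiles:
        row: dict[str, object] = {
            "state": ep.state,
            "subject": ep.subject,
            "epoch": ep.epoch_index,
        }
        for est in estimators:
            for band in bands:
                key = (est, band)
                if key not in prof_map:
                    raise ValueError(
                        f"epoch (subject={ep.subject}, state={ep.state}, "
                        f"index={ep.epoch_index}) missing profile for {key}"
                    )
                row.update(prof_map[key].as_features())
        rows.append(row)
    table = pd.DataFrame(rows)
    feat_cols = [c for c in table.columns if c not in META_COLUMNS]
    if not np.isfinite(table[feat_cols].to_numpy(dtype=float)).all():
        raise ValueError("feature table contains non-finite values")
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in META_COLUMNS]


def select_features(
    table: pd.DataFrame,
    estimators: Sequence[str] | None = None,
    bands: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Restrict the table to a feature subset (e.g. SL-only, SL+PLV, ...)."""
    estimators = list(estimators or ESTIMATORS)
    bands = list(bands or BAND_ORDER)
    keep = [
        c
        for c in feature_columns(table)
        if c.split("_")[0] in estimators and c.split("_")[1] in bands
    ]
    if not keep:
        raise ValueError(f"no features match estimators={estimators}, bands={bands}")
    return table[list(META_COLUMNS) + keep]


def make_classifier(name: str, seed: int = 0):
    """Classifier factory with fixed, documented defaults.

    knn: k=10 neighbors, Euclidean distance (the common "medium" preset).
    rf: 200 trees.  gboost: XGBoost, 200 rounds, depth 3, eta 0.1.
    svm: RBF (Gaussian) kernel with probability estimates.
    """
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=10, metric="euclidean")
    if name == "rf":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if name == "gboost":
        return XGBClassifier(
            n_estimators=200,
            max_depth=3,
            learning_rate=0.1,
            subsample=0.9,
            random_state=seed,
            eval_metric="logloss",
            n_jobs=1,
        )
    if name == "svm":
        return SVC(kernel="rbf", probability=True, random_state=seed)
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


@dataclass
class RecognitionReport:
    """Classification outcome: CV metrics, held-out metrics, ROC, importances."""

    task: str
    classifier: str
    classes: list[str]
    feature_names: list[str]
    cv_scores: np.ndarray
    cv_accuracy: float
    test_accuracy: float
    precision: float
    recall: float
    f1: float
    confusion: np.ndarray
    roc_auc: dict[str, float]
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    cv_config: dict[str, object]
    model: Pipeline = field(repr=False, default=None)

    def summary(self) -> str:
        lines = [
            f"{self.classifier} ({self.task} task, classes: {', '.join(self.classes)})",
            f"  CV accuracy (10-fold): {self.cv_accuracy:.3f} "
            f"(+/- {self.cv_scores.std():.3f})",
            f"  Held-out test: Acc={self.test_accuracy:.3f} P={self.precision:.3f} "
            f"Re={self.recall:.3f} F1={self.f1:.3f}",
            "  ROC AUC (one-vs-rest): "
            + ", ".join(f"{c}={a:.3f}" for c, a in self.roc_auc.items()),
        ]
        return "\n".join(lines)


def _binary_labels(states: pd.Series) -> pd.Series:
    return states.map(lambda s: "normal" if s == "normal" else "distracted")


def train_evaluate(
    table: pd.DataFrame,
    task: str = "ternary",
    classifier: str = "gboost",
    seed: int = 0,
    split: str = "epoch",
    test_fraction: float = 0.1,
    n_folds: int = 10,
) -> RecognitionReport:
    """Train and evaluate one classifier on the feature table.

    ``task="binary"`` relabels cognitive+visual as ``distracted``.
    ``split="subject"`` groups all epochs of a subject on one side of the
    outer split and uses group-stratified CV folds; ``split="epoch"``
    stratifies per epoch.
    """
    if task not in TASKS:
        raise ValueError(f"task must be one of {TASKS}, got {task!r}")
    if split not in ("epoch", "subject"):
        raise ValueError(f"split must be 'epoch' or 'subject', got {split!r}")
    feats = feature_columns(table)
    X = table[feats].to_numpy(dtype=float)
    y_raw = table["state"] if task == "ternary" else _binary_labels(table["state"])
    le = LabelEncoder()
    y = le.fit_transform(y_raw)
    groups = table["subject"].to_numpy()

    counts = np.bincount(y)
    if (counts < 2).any():
        raise ValueError(
            "each class needs at least 2 samples; resample the cohort with more "
            f"epochs per state (counts: {dict(zip(le.classes_, counts))})"
        )

    if split == "epoch":
        n_test = max(int(round(test_fraction * len(y))), len(le.classes_))
        idx_dev, idx_test = train_test_split(
            np.arange(len(y)),
            test_size=n_test,
            stratify=y,
            random_state=seed,
        )
        min_class = int(np.bincount(y[idx_dev]).min())
        if min_class < 2:
            raise ValueError(
                "a class has fewer than 2 development samples after the test "
                "reserve; resample the cohort with more epochs per state"
            )
        cv = StratifiedKFold(
            n_splits=max(2, min(n_folds, min_class)), shuffle=True, random_state=seed
        )
        cv_groups = None
    else:
        gss = GroupShuffleSplit(n_splits=1, test_size=test_fraction, random_state=seed)
        idx_dev, idx_test = next(gss.split(X, y, groups))
        n_dev_groups = len(np.unique(groups[idx_dev]))
        cv = StratifiedGroupKFold(n_splits=min(n_folds, n_dev_groups))
        cv_groups = groups[idx_dev]

    pipe = Pipeline(
        [("scale", StandardScaler()), ("clf", make_classifier(classifier, seed))]
    )
    cv_scores = cross_val_score(
        pipe, X[idx_dev], y[idx_dev], cv=cv, groups=cv_groups, scoring="accuracy"
    )

    pipe.fit(X[idx_dev], y[idx_dev])
    y_pred = pipe.predict(X[idx_test])
    y_true = y[idx_test]
    avg = "binary" if len(le.classes_) == 2 else "macro"
    pos_label = None
    if avg == "binary":
        # report the distracted class as positive
        pos_label = int(np.flatnonzero(le.classes_ == "distracted")[0])
    kw = {"average": avg} if avg == "macro" else {"average": avg, "pos_label": pos_label}
    proba = pipe.predict_proba(X[idx_test])
    roc_auc: dict[str, float] = {}
    roc_curves: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ci, cname in enumerate(le.classes_):
        y_bin = (y_true == ci).astype(int)
        if y_bin.min() == y_bin.max():
            roc_auc[cname] = float("nan")
            continue
        roc_auc[cname] = float(roc_auc_score(y_bin, proba[:, ci]))
        fpr, tpr, _ = roc_curve(y_bin, proba[:, ci])
        roc_curves[cname] = (fpr, tpr)

    return RecognitionReport(
        task=task,
        classifier=classifier,
        classes=list(le.classes_),
        feature_names=feats,
        cv_scores=cv_scores,
        cv_accuracy=float(cv_scores.mean()),
        test_accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(precision_score(y_true, y_pred, zero_division=0, **kw)),
        recall=float(recall_score(y_true, y_pred, zero_division=0, **kw)),
        f1=float(f1_score(y_true, y_pred, zero_division=0, **kw)),
        confusion=confusion_matrix(y_true, y_pred),
        roc_auc=roc_auc,
        roc_curves=roc_curves,
        cv_config={
            "n_folds": n_folds,
            "test_fraction": test_fraction,
            "split": split,
            "seed": seed,
        },
        model=pipe,
    )


@dataclass
class ImportanceReport:
    """Normalized per-feature importances with estimator and band shares."""

    ranking: pd.DataFrame  # columns: feature, importance (descending)
    estimator_share: dict[str, float]
    band_share: dict[str, float]


def feature_importance(report: RecognitionReport) -> ImportanceReport:
    """Feature-importance ranking from a fitted tree-ensemble report.

    Importances are normalized to sum to 1 and aggregated into shares per
    connectivity estimator (SL/PLV/COH) and per band.
    """
    clf = report.model.named_steps["clf"]
    if not hasattr(clf, "feature_importances_"):
        raise ValueError(
            f"classifier {report.classifier!r} exposes no feature importances; "
            "use a tree ensemble (rf or gboost)"
        )
    imp = np.asarray(clf.feature_importances_, dtype=float)
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    ranking = (
        pd.DataFrame({"feature": report.feature_names, "importance": imp})
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    est_share: dict[str, float] = {}
    band_share: dict[str, float] = {}
    for name, w in zip(report.feature_names, imp):
        est, band, _ = name.split("_", 2)
        est_share[est] = est_share.get(est, 0.0) + float(w)
        band_share[band] = band_share.get(band, 0.0) + float(w)
    return ImportanceReport(ranking, est_share, band_share)
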