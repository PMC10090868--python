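"""Classifier training, validation protocol and the metric set.

Three classifier configurations are supported: a random-subspace ensemble
of K-nearest-neighbour learners (K picked from a grid by validation error),
a cubic-polynomial-kernel SVM, and a bagged ensemble of decision trees.
The validation protocol is a stratified 70/30 split repeated five times
with results averaged, optional 10-fold cross-validated model selection on
the training part, and a subject-specific variant that trains and tests
within each subject.

Feature selection and standardisation are always fit on the training
partition only and applied unchanged to the test partition.

Metrics per one-vs-rest class: accuracy = 100*(TP+TN)/total, sensitivity =
100*TP/(TP+FN), specificity = 100*TN/(TN+FP), precision = 100*TP/(TP+FP),
and an F-score defined as the harmonic mean of sensitivity and specificity
(the method's variant; the standard F1 of precision and recall is available
via ``fscore="f1"``).  Multi-class overall accuracy is trace/total,
per-class accuracy is the recall of that class, and AUC is the macro
one-vs-rest area from prediction scores.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import BaggingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import (StratifiedKFold, StratifiedShuffleSplit,
                                     cross_val_score, train_test_split)
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES
from .selection import select_features
from .stages import SCHEME_CLASSES, merge_stages

MODEL_KINDS = ("subspace_knn", "svm_poly", "bagged_rf")


@dataclass(frozen=True)
class ModelSpec:
    """Configuration of one classifier backend."""

    kind: str = "svm_poly"
    K: int = 10
    distance: str = "cubic"  # Minkowski p=3; or "weighted_euclidean"
    svm_degree: int = 3
    n_learners: int = 30
    subspace_dim: int | None = None  # default ceil(d/2)
    n_trees: int = 100
    k_grid: Sequence[int] = (3, 5, 7, 10, 15)
    seed: int = 0

    def validate(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if self.K < 1 or self.n_learners < 1 or self.n_trees < 1:
            raise ValueError("K, n_learners and n_trees must be >= 1")


@dataclass
class ConfusionMatrix:
    """Class-by-class count table; rows are truth, columns predictions."""

    classes: tuple[str, ...]
    counts: np.ndarray

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes) -> "ConfusionMatrix":
        classes = tuple(classes)
        lut = {c: i for i, c in enumerate(classes)}
        counts = np.zeros((len(classes), len(classes)), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[lut[t], lut[p]] += 1
        return cls(classes=classes, counts=counts)

    def ovr(self, cls_name: str) -> tuple[int, int, int, int]:
        """One-vs-rest (TP, TN, FP, FN) of one class."""
        i = self.classes.index(cls_name)
        tp = int(self.counts[i, i])
        fn = int(self.counts[i].sum() - tp)
        fp = int(self.counts[:, i].sum() - tp)
        tn = int(self.counts.sum() - tp - fn - fp)
        return tp, tn, fp, fn


def _knn(spec: ModelSpec, K: int) -> KNeighborsClassifier:
    if spec.distance == "cubic":
        return KNeighborsClassifier(n_neighbors=K, metric="minkowski", p=3)
    if spec.distance == "weighted_euclidean":
        return KNeighborsClassifier(n_neighbors=K, weights="distance")
    raise ValueError(f"unknown distance {spec.distance!r}")


def _pick_k(spec: ModelSpec, X: np.ndarray, y: np.ndarray) -> int:
    """Choose K from the grid by hold-out validation error."""
    grid = [k for k in spec.k_grid if k < len(y)]
    if len(grid) <= 1:
        return grid[0] if grid else 1
    try:
        xtr, xva, ytr, yva = train_test_split(
            X, y, test_size=0.25, stratify=y, random_state=spec.seed)
    except ValueError:
        xtr, xva, ytr, yva = train_test_split(
            X, y, test_size=0.25, random_state=spec.seed)
    best_k, best_acc = grid[0], -1.0
    for k in grid:
        if k > len(ytr):
            continue
        acc = _knn(spec, k).fit(xtr, ytr).score(xva, yva)
        if acc > best_acc:
            best_k, best_acc = k, acc
    return best_k


class _SubspaceKNN(ClassifierMixin, BaseEstimator):
    """Random-subspace KNN ensemble with data-driven K (majority vote)."""

    def __init__(self, spec: ModelSpec = ModelSpec(kind="subspace_knn")):
        self.spec = spec

    def fit(self, X, y):
        X = np.asarray(X)
        k = _pick_k(self.spec, X, np.asarray(y))
        d = X.shape[1]
        dim = self.spec.subspace_dim or max(1, math.ceil(d / 2))
        self.model_ = BaggingClassifier(
            estimator=_knn(self.spec, k),
            n_estimators=self.spec.n_learners,
            max_samples=1.0, bootstrap=False,
            max_features=min(dim, d), bootstrap_features=False,
            random_state=self.spec.seed)
        self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        self.chosen_k_ = k
        return self

    def predict(self, X):
        return self.model_.predict(X)

    def predict_proba(self, X):
        return self.model_.predict_proba(X)


def build_model(spec: ModelSpec) -> Pipeline:
    """Standardisation (training statistics only) followed by the classifier."""
    spec.validate()
    if spec.kind == "subspace_knn":
        clf = _SubspaceKNN(spec)
    elif spec.kind == "svm_poly":
        clf = SVC(kernel="poly", degree=spec.svm_degree, gamma="scale",
                  coef0=1.0, decision_function_shape="ovr",
                  random_state=spec.seed)
    else:  # bagged_rf
        clf = BaggingClassifier(
            estimator=DecisionTreeClassifier(random_state=spec.seed),
            n_estimators=spec.n_trees, bootstrap=True,
            random_state=spec.seed)
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def train(spec: ModelSpec, X, y) -> Pipeline:
    """Fit the configured classifier on already-selected features."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) != len(y):
        raise ValueError(f"feature/label length mismatch: {len(X)} vs {len(y)}")
    return build_model(spec).fit(X, y)


def split_70_30(labels, repeats: int = 5, seed: int = 0,
                test_size: float = 0.3) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified random 70/30 index splits, repeated with distinct streams."""
    y = np.asarray(labels)
    splitter = StratifiedShuffleSplit(n_splits=repeats, test_size=test_size,
                                      random_state=seed)
    splits = []
    for tr, te in splitter.split(np.zeros((len(y), 1)), y):
        if set(y[tr]) != set(y):
            warnings.warn("a class is absent from a training split")
        splits.append((tr, te))
    return splits


def kfold_select(X, y, grid: Sequence[ModelSpec], k: int = 10,
                 seed: int = 0) -> ModelSpec:
    """Pick the ModelSpec with the best k-fold cross-validated accuracy.

    Ties go to the simpler model (fewer learners, then lower K).
    """
    if not grid:
        raise ValueError("empty model grid")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    k_eff = min(k, int(counts.min()))
    cv = StratifiedKFold(n_splits=max(2, k_eff), shuffle=True, random_state=seed)
    scored = []
    for spec in grid:
        acc = cross_val_score(build_model(spec), X, y, cv=cv,
                              scoring="accuracy").mean()
        n_learners = spec.n_learners if spec.kind == "subspace_knn" else (
            spec.n_trees if spec.kind == "bagged_rf" else 1)
        scored.append((-acc, n_learners, spec.K, spec))
    scored.sort(key=lambda t: t[:3])
    return scored[0][3]


def _scores(model: Pipeline, X: np.ndarray) -> np.ndarray | None:
    clf = model
    if hasattr(clf, "predict_proba"):
        try:
            return np.asarray(clf.predict_proba(X))
        except AttributeError:
            pass
    if hasattr(clf, "decision_function"):
        s = np.asarray(clf.decision_function(X))
        if s.ndim == 1:
            s = np.column_stack([-s, s])
        return s
    return None


def macro_ovr_auc(y_true, scores: np.ndarray | None, classes) -> float:
    """Macro-averaged one-vs-rest AUC from per-class prediction scores."""
    if scores is None:
        return np.nan
    y_true = np.asarray(y_true)
    aucs = []
    for i, c in enumerate(classes):
        mask = (y_true == c).astype(int)
        if mask.min() == mask.max():
            continue
        aucs.append(roc_auc_score(mask, scores[:, i]))
    return float(np.mean(aucs)) if aucs else np.nan


def compute_metrics(cm: ConfusionMatrix, fscore: str = "paper") -> dict:
    """The metric set from a confusion matrix.

    Returns overall accuracy, per-class accuracy (recall), and macro
    one-vs-rest sensitivity/specificity/precision/F-score, all in percent.
    Zero-denominator ratios come out non-finite.
    """
    total = cm.counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    out: dict = {"overall_accuracy": 100.0 * np.trace(cm.counts) / total,
                 "per_class": {}}
    macro = {"sensitivity": [], "specificity": [], "precision": [], "fscore": []}
    for c in cm.classes:
        tp, tn, fp, fn = cm.ovr(c)
        sens = 100.0 * tp / (tp + fn) if tp + fn else np.nan
        spec = 100.0 * tn / (tn + fp) if tn + fp else np.nan
        prec = 100.0 * tp / (tp + fp) if tp + fp else np.nan
        acc = 100.0 * (tp + tn) / total
        if fscore == "paper":
            fs = (2.0 * sens * spec / (sens + spec)
                  if np.isfinite(sens) and np.isfinite(spec) and sens + spec > 0
                  else np.nan)
        else:
            fs = (2.0 * prec * sens / (prec + sens)
                  if np.isfinite(prec) and np.isfinite(sens) and prec + sens > 0
                  else np.nan)
        out["per_class"][c] = {"accuracy": acc, "sensitivity": sens,
                               "specificity": spec, "precision": prec,
                               "fscore": fs}
        for key, val in (("sensitivity", sens), ("specificity", spec),
                         ("precision", prec), ("fscore", fs)):
            macro[key].append(val)
    for key, vals in macro.items():
        out[key] = float(np.nanmean(vals))
    return out


@dataclass
class EvalReport:
    """Aggregated evaluation over splits of one scheme/model combination."""

    scheme: str
    model_kind: str
    split_metrics: list[dict] = field(default_factory=list)
    confusions: list[ConfusionMatrix] = field(default_factory=list)
    selected_counts: list[int] = field(default_factory=list)
    seed: int = 0

    def aggregate(self) -> dict:
        keys = ("overall_accuracy", "sensitivity", "specificity",
                "precision", "fscore", "auc")
        agg = {}
        for k in keys:
            vals = np.array([m[k] for m in self.split_metrics], dtype=float)
            agg[k] = {"mean": float(np.nanmean(vals)),
                      "sd": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0}
        classes = self.confusions[0].classes if self.confusions else ()
        agg["per_class_accuracy"] = {
            c: {"mean": float(np.nanmean(
                [m["per_class"][c]["accuracy"] for m in self.split_metrics]))}
            for c in classes}
        return agg

    def to_json(self, path) -> None:
        payload = {"scheme": self.scheme, "model": self.model_kind,
                   "seed": self.seed,
                   "aggregate": self.aggregate(),
                   "splits": self.split_metrics,
                   "confusions": [{"classes": list(c.classes),
                                   "counts": c.counts.tolist()}
                                  for c in self.confusions]}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=float)


def _detrend_features(df: pd.DataFrame) -> pd.DataFrame:
    """Remove the per-subject linear trend across the night per feature."""
    out = df.copy()
    for _, idx in df.groupby("subject_id").groups.items():
        block = out.loc[idx, list(FEATURE_NAMES)].to_numpy(dtype=float)
        ok_rows = np.all(np.isfinite(block), axis=1)
        if ok_rows.sum() >= 3:
            block[ok_rows] = _signal.detrend(block[ok_rows], axis=0)
            out.loc[idx, list(FEATURE_NAMES)] = block
    return out


def prepare_matrix(features: pd.DataFrame, scheme: str, detrend: bool = True
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Drop invalid epochs, merge labels to the scheme, optionally detrend."""
    df = features[features["valid"]].reset_index(drop=True)
    if detrend:
        df = _detrend_features(df)
    X = df[list(FEATURE_NAMES)]
    y = np.asarray(merge_stages(df["label"].tolist(), scheme))
    return df, y


def evaluate_split(spec: ModelSpec, X: pd.DataFrame, y: np.ndarray,
                   train_idx: np.ndarray, test_idx: np.ndarray,
                   scheme: str, alpha: float = 0.05,
                   do_select: bool = True) -> tuple[dict, ConfusionMatrix, int]:
    """Select features and fit on the training part; score the test part."""
    xtr, ytr = X.iloc[train_idx], y[train_idx]
    xte, yte = X.iloc[test_idx], y[test_idx]
    if do_select:
        report = select_features(xtr, ytr, scheme, alpha)
        cols = report.selected_features or list(X.columns)
    else:
        cols = list(X.columns)
    model = train(spec, xtr[cols].to_numpy(), ytr)
    pred = model.predict(xte[cols].to_numpy())
    classes = tuple(c for c in SCHEME_CLASSES[scheme] if c in set(y))
    cm = ConfusionMatrix.from_predictions(yte, pred, classes)
    metrics = compute_metrics(cm)
    model_classes = list(model.classes_)
    scores = _scores(model, xte[cols].to_numpy())
    if scores is not None:
        order = [model_classes.index(c) for c in classes]
        scores = scores[:, order]
    metrics["auc"] = macro_ovr_auc(yte, scores, classes)
    return metrics, cm, len(cols)


def run_generic_eval(features: pd.DataFrame, scheme: str, spec: ModelSpec,
                     repeats: int = 5, seed: int = 0, alpha: float = 0.05,
                     do_select: bool = True, detrend: bool = True
                     ) -> EvalReport:
    """The pooled-epoch protocol: 5 stratified 70/30 splits, averaged."""
    X_df, y = prepare_matrix(features, scheme, detrend=detrend)
    X = X_df[list(FEATURE_NAMES)]
    report = EvalReport(scheme=scheme, model_kind=spec.kind, seed=seed)
    for i, (tr, te) in enumerate(split_70_30(y, repeats=repeats, seed=seed)):
        split_seed = ((seed + 1) * 101 + i) % (2 ** 31)
        split_spec = ModelSpec(**{**asdict(spec), "seed": split_seed})
        m, cm, ncols = evaluate_split(split_spec, X, y, tr, te, scheme,
                                      alpha, do_select)
        report.split_metrics.append(m)
        report.confusions.append(cm)
        report.selected_counts.append(ncols)
    return report


def subject_specific_eval(features: pd.DataFrame, scheme: str,
                          spec: ModelSpec, seed: int = 0,
                          alpha: float = 0.05, do_select: bool = True
                          ) -> dict[str, EvalReport]:
    """Train and test inside each subject (70/30 within-subject split)."""
    out: dict[str, EvalReport] = {}
    for sid, block in features.groupby("subject_id"):
        X_df, y = prepare_matrix(block.reset_index(drop=True), scheme)
        if len(set(y)) < 2 or min(np.bincount(pd.factorize(y)[0])) < 4:
            warnings.warn(f"subject {sid}: not enough classes/epochs; skipped")
            continue
        X = X_df[list(FEATURE_NAMES)]
        rep = EvalReport(scheme=scheme, model_kind=spec.kind, seed=seed)
        for i, (tr, te) in enumerate(split_70_30(y, repeats=1, seed=seed)):
            m, cm, _ = evaluate_split(
                ModelSpec(**{**asdict(spec), "seed": seed + i}),
                X, y, tr, te, scheme, alpha, do_select)
            rep.split_metrics.append(m)
            rep.confusions.append(cm)
        out[sid] = rep
    return out
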