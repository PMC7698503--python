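"""Feature scaling, the four-classifier harness, and the binary metrics.

Classifiers: linear discriminant analysis (LDA), an RBF support vector
machine (SVM), gradient-boosted trees (XGBoost) and a random forest (RF).
No hyperparameters are prescribed by the method itself, so widely used
defaults are fixed here and exposed through ``make_classifier``.

Evaluation is stratified k-fold (default 10) with per-fold [-1, 1]
min-max scaling fitted on the training split only; confusion counts are
pooled over folds (micro), and the four metrics are

    F1  = 2TP / (2TP + FP + FN) * 100
    Acc = (TP + TN) / (TP + FP + FN + TN) * 100
    Sp  = TN / (TN + FP) * 100
    Se  = TP / (TP + FN) * 100

with class 1 (state elicited) as the positive class.  A zero denominator
yields a NaN sentinel with a warning, never an exception.

``paper_faithful=True`` switches to scaling fitted once on the full
matrix before cross-validation, reproducing the global-normalisation
variant of the protocol at the cost of a small train/test leak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .errors import ConfigurationError, ValidationError
from .io_core import FeatureMatrix

logger = logging.getLogger(__name__)

CLASSIFIER_NAMES = ("LDA", "SVM", "XGBoost", "RF")


@dataclass
class ConfusionCounts:
    """Pooled binary confusion counts (positive class = 1)."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def add_predictions(self, y_true: np.ndarray, y_pred: np.ndarray) -> None:
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        self.tp += int(np.sum((y_true == 1) & (y_pred == 1)))
        self.fp += int(np.sum((y_true == 0) & (y_pred == 1)))
        self.fn += int(np.sum((y_true == 1) & (y_pred == 0)))
        self.tn += int(np.sum((y_true == 0) & (y_pred == 0)))


@dataclass
class ClassifierReport:
    """One evaluation run: classifier, metrics (%) and provenance."""

    classifier: str
    f1: float
    acc: float
    se: float
    sp: float
    counts: ConfusionCounts
    selected_features: tuple[int, ...] | None = None
    folds: int = 10
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "classifier": self.classifier,
            "f1": self.f1, "acc": self.acc, "se": self.se, "sp": self.sp,
            "selected_features": (list(self.selected_features)
                                  if self.selected_features is not None else None),
            "folds": self.folds, "seed": self.seed,
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "fn": self.counts.fn, "tn": self.counts.tn},
        }


class RangeScaler:
    """Affine per-feature map sending train min to -1 and train max to +1.

    Held-out values may land outside [-1, 1]; constant training columns
    map to 0 everywhere (with a warning), since the map is undefined.
    """

    def __init__(self):
        self.min_: np.ndarray | None = None
        self.max_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "RangeScaler":
        X = np.asarray(X, dtype=float)
        self.min_ = X.min(axis=0)
        self.max_ = X.max(axis=0)
        if np.any(self.max_ == self.min_):
            logger.warning("constant training column(s) scaled to 0")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        span = self.max_ - self.min_
        out = np.zeros_like(X)
        ok = span > 0
        out[:, ok] = -1.0 + 2.0 * (X[:, ok] - self.min_[ok]) / span[ok]
        return out

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


def scale_features(train: np.ndarray, apply_to: np.ndarray) -> np.ndarray:
    """Fit the [-1, 1] range map on *train* and apply it to *apply_to*."""
    return RangeScaler().fit(np.atleast_2d(train)).transform(np.atleast_2d(apply_to))


def make_classifier(name: str, seed: int = 0):
    """Instantiate one of the four supported classifiers by name."""
    if name == "LDA":
        return LinearDiscriminantAnalysis()
    if name == "SVM":
        return SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    if name == "XGBoost":
        return XGBClassifier(n_estimators=100, max_depth=3, learning_rate=0.1,
                             random_state=seed, n_jobs=1, verbosity=0,
                             eval_metric="logloss")
    if name == "RF":
        return RandomForestClassifier(n_estimators=100, random_state=seed, n_jobs=1)
    raise ConfigurationError(
        f"unknown classifier {name!r}; choose one of {list(CLASSIFIER_NAMES)}"
    )


def compute_metrics(cc: ConfusionCounts) -> tuple[float, float, float, float]:
    """(F1, Acc, Se, Sp) as percentages; NaN where a denominator is zero."""
    def ratio(num: float, den: float, what: str) -> float:
        if den == 0:
            logger.warning("metric %s undefined (zero denominator)", what)
            return float("nan")
        return 100.0 * num / den

    f1 = ratio(2 * cc.tp, 2 * cc.tp + cc.fp + cc.fn, "F1")
    acc = ratio(cc.tp + cc.tn, cc.total, "Acc")
    se = ratio(cc.tp, cc.tp + cc.fn, "Se")
    sp = ratio(cc.tn, cc.tn + cc.fp, "Sp")
    return f1, acc, se, sp


def cv_confusion(X: np.ndarray, y: np.ndarray, classifier_name: str,
                 folds: int = 10, seed: int = 0,
                 fold_indices: list[tuple[np.ndarray, np.ndarray]] | None = None,
                 paper_faithful: bool = False) -> ConfusionCounts:
    """Pooled confusion counts from stratified k-fold cross-validation."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ValidationError("X must be 2-D")
    if set(np.unique(y)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    if fold_indices is None:
        fold_indices = make_folds(y, folds, seed)
    global_scaler = RangeScaler().fit(X) if paper_faithful else None
    cc = ConfusionCounts()
    # a classifier spec is a registered name or a ready estimator instance
    base = (make_classifier(classifier_name, seed)
            if isinstance(classifier_name, str) else classifier_name)
    for train_idx, test_idx in fold_indices:
        if len(np.unique(y[train_idx])) < 2:
            raise ValidationError("a class is absent from a training fold")
        if paper_faithful:
            Xtr = global_scaler.transform(X[train_idx])
            Xte = global_scaler.transform(X[test_idx])
        else:
            scaler = RangeScaler().fit(X[train_idx])
            Xtr = scaler.transform(X[train_idx])
            Xte = scaler.transform(X[test_idx])
        model = clone(base)
        model.fit(Xtr, y[train_idx])
        cc.add_predictions(y[test_idx], model.predict(Xte))
    return cc


def make_folds(y: np.ndarray, folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified fold indices with a fixed shuffle seed."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def evaluate_classifier(fm: FeatureMatrix, classifier_name: str,
                        feature_subset: tuple[int, ...] | None = None,
                        folds: int = 10, seed: int = 0,
                        paper_faithful: bool = False) -> ClassifierReport:
    """Cross-validated metrics for one classifier.

    *feature_subset* holds 1-based feature IDs; ``None`` means all 26.
    """
    if feature_subset is not None:
        cols = [fid - 1 for fid in feature_subset]
        X = fm.values[:, cols]
    else:
        X = fm.values
    cc = cv_confusion(X, fm.labels, classifier_name, folds, seed,
                      paper_faithful=paper_faithful)
    f1, acc, se, sp = compute_metrics(cc)
    return ClassifierReport(classifier_name, f1, acc, se, sp, cc,
                            selected_features=(tuple(feature_subset)
                                               if feature_subset else None),
                            folds=folds, seed=seed)


def run_comparison(fm: FeatureMatrix,
                   classifiers: tuple[str, ...] = CLASSIFIER_NAMES,
                   with_selection: bool = False, folds: int = 10,
                   seed: int = 0, paper_faithful: bool = False) -> list[ClassifierReport]:
    """Evaluate each classifier, optionally on its own selected subset.

    With selection enabled, backward floating selection runs once per
    classifier and the classifier is then evaluated on its optimal
    subset; without it, all 26 features are used.
    """
    from .selection import sbfs  # local import: selection builds on this module

    reports = []
    for name in classifiers:
        if with_selection:
            result = sbfs(fm, name, folds=folds, seed=seed,
                          paper_faithful=paper_faithful)
            subset = result.best_subset
            rep = evaluate_classifier(fm, name, feature_subset=subset,
                                      folds=folds, seed=seed,
                                      paper_faithful=paper_faithful)
        else:
            rep = evaluate_classifier(fm, name, folds=folds, seed=seed,
                                      paper_faithful=paper_faithful)
        reports.append(rep)
    return reports


def reports_to_markdown(reports: list[ClassifierReport], title: str) -> str:
    """Render reports as a compact Markdown table."""
    lines = [f"### {title}", "",
             "| Classifier | F1 (%) | Acc (%) | Se (%) | Sp (%) | Selected Features |",
             "|---|---|---|---|---|---|"]
    for r in reports:
        sel = (", ".join(map(str, r.selected_features))
               if r.selected_features else "—")
        lines.append(f"| {r.classifier} | {r.f1:.2f} | {r.acc:.2f} "
                     f"| {r.se:.2f} | {r.sp:.2f} | {sel} |")
    return "\n".join(lines) + "\n"
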