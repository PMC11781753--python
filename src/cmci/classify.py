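"""Classifier bench: stratified splitting, four classifiers, ROC evaluation.

The bench compares a Ranking Forest — 50 bagged CART trees with random
feature subsetting whose averaged positive-class vote serves as a ranking
score — against Gaussian Naive Bayes, L2 logistic regression and an
RBF-kernel soft-margin SVM, on per-condition feature tables.  Evaluation
is by ROC: the AUC is the exact trapezoidal area (equivalently the
Mann-Whitney pairwise-ordering statistic with ties counted half), and
sensitivity/specificity are reported at the Youden-optimal operating point
(max TPR - FPR, ties broken toward the lower threshold).  Both a single
stratified 70/30 split and stratified k-fold cross-validation (default 10
folds) are provided.

Baseline classifiers see z-scored features whose scaling statistics come
from the training fold only; trees are scale-invariant and consume raw
features.  The standard estimators are scikit-learn's, wrapped so every
model exposes one continuous scoring interface.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DegenerateModelError, EvaluationError, StratificationError
from .features import FeatureTable

__all__ = [
    "CLASSIFIERS",
    "SplitPlan",
    "Scorer",
    "EvaluationResult",
    "stratified_split",
    "train_ranking_forest",
    "train_baselines",
    "train_classifier",
    "evaluate",
    "cross_validate",
]

CLASSIFIERS = ("ranking_forest", "naive_bayes", "logistic", "svm")

#: Single-letter prefixes used in result names (R_CMCI_COPLen etc.).
CLASSIFIER_LETTER = {
    "ranking_forest": "R",
    "naive_bayes": "B",
    "logistic": "L",
    "svm": "S",
}

DEFAULT_N_TREES = 50
DEFAULT_TRAIN_FRACTION = 0.7


# ---------------------------------------------------------------------------
# data plumbing

def _as_xy(data, y=None, positive_label=None):
    """Accept a FeatureTable or (X, y) arrays; return X, y, positive label.

    Rows with NaN feature cells (undefined CMCI flags) are dropped with a
    warning — classifiers cannot consume them.
    """
    if isinstance(data, FeatureTable):
        X = data.matrix()
        y = data.labels
    else:
        X = np.asarray(data, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if y is None:
            raise ValueError("labels required when passing a bare matrix")
        y = np.asarray(y)
    keep = np.all(np.isfinite(X), axis=1)
    if not np.all(keep):
        warnings.warn(f"dropping {int(np.sum(~keep))} row(s) with undefined "
                      "feature values", stacklevel=3)
        X, y = X[keep], y[keep]
    classes = np.unique(y)
    if positive_label is None:
        positive_label = "elite" if "elite" in classes else classes[-1]
    return X, y, positive_label


@dataclass
class SplitPlan:
    """A stratified train/test partition of row indices."""

    train_indices: np.ndarray
    test_indices: np.ndarray
    train_fraction: float
    seed: int
    stratified: bool = True


def stratified_split(labels, train_fraction: float = DEFAULT_TRAIN_FRACTION,
                     seed: int = 0) -> SplitPlan:
    """Seeded per-class split keeping class proportions in both parts.

    Each class is shuffled with the given seed and the first
    ``round(train_fraction * class_size)`` samples (banker's rounding, as
    Python's :func:`round`) go to training.  Raises
    :class:`StratificationError` for classes with < 2 samples or fractions
    that empty either part.
    """
    labels = np.asarray(labels)
    if not 0 < train_fraction < 1:
        raise StratificationError(
            f"train_fraction must be in (0, 1), got {train_fraction}"
        )
    rng = np.random.default_rng(seed)
    train_parts, test_parts = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if idx.size < 2:
            raise StratificationError(
                f"class {cls!r} has {idx.size} sample(s); need >= 2"
            )
        idx = rng.permutation(idx)
        n_train = round(train_fraction * idx.size)
        if n_train < 1 or n_train >= idx.size:
            raise StratificationError(
                f"fraction {train_fraction} empties train or test for class "
                f"{cls!r} (size {idx.size})"
            )
        train_parts.append(idx[:n_train])
        test_parts.append(idx[n_train:])
    return SplitPlan(
        train_indices=np.sort(np.concatenate(train_parts)),
        test_indices=np.sort(np.concatenate(test_parts)),
        train_fraction=train_fraction,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# classifiers

@dataclass
class Scorer:
    """A fitted classifier exposing one continuous ranking score."""

    name: str
    model: object
    positive_label: object
    score_kind: str  # "proba" | "decision"

    def scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.score_kind == "proba":
            classes = list(self.model.classes_)
            col = classes.index(self.positive_label)
            return self.model.predict_proba(X)[:, col]
        return np.asarray(self.model.decision_function(X), dtype=float)


def _check_classes(y, positive_label):
    classes = np.unique(y)
    if classes.size < 2:
        raise DegenerateModelError(
            f"training set contains a single class {classes[0]!r}"
        )
    if positive_label not in classes:
        raise DegenerateModelError(
            f"positive label {positive_label!r} absent from training labels"
        )


def train_ranking_forest(train, y=None, n_trees: int = DEFAULT_N_TREES,
                         seed: int = 0, positive_label=None) -> Scorer:
    """Fit the Ranking Forest: bagged CART trees as a ranking scorer.

    Each of the ``n_trees`` trees is grown on a bootstrap resample of the
    training rows with sqrt(p) candidate features per split (Gini impurity,
    unlimited depth, min leaf 1).  Trees grown to purity vote 0/1, so the
    averaged positive-class probability equals the fraction of trees voting
    positive — the ranking score.
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    X, y, positive_label = _as_xy(train, y, positive_label)
    _check_classes(y, positive_label)
    model = RandomForestClassifier(
        n_estimators=n_trees,
        criterion="gini",
        max_depth=None,
        min_samples_leaf=1,
        max_features="sqrt",
        bootstrap=True,
        random_state=seed,
    )
    model.fit(X, y)
    return Scorer(name="ranking_forest", model=model,
                  positive_label=positive_label, score_kind="proba")


def train_baselines(train, y=None, which: str = "naive_bayes", seed: int = 0,
                    positive_label=None) -> Scorer:
    """Fit one baseline classifier on z-scored features.

    ``naive_bayes``: Gaussian NB (score = positive-class posterior; feature
    variances are floored via a 1e-9 smoothing term, with a warning if a
    training feature is exactly constant).  ``logistic``: L2-regularized
    logistic regression (score = positive-class probability).  ``svm``:
    soft-margin SVC with RBF kernel, C = 1, gamma = 1 / (p * var) (score =
    signed decision value).  Scaling statistics come from the training data
    handed in — never from test rows.
    """
    X, y, positive_label = _as_xy(train, y, positive_label)
    _check_classes(y, positive_label)
    if which == "naive_bayes":
        if np.any(np.var(X, axis=0) == 0):
            warnings.warn("zero-variance feature under Naive Bayes; "
                          "variance floored by smoothing", stacklevel=2)
        est = GaussianNB(var_smoothing=1e-9)
        kind = "proba"
    elif which == "logistic":
        # default penalty is the L2 ridge; C = 1
        est = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000,
                                 random_state=seed)
        kind = "proba"
    elif which == "svm":
        est = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
        kind = "decision"
    else:
        raise ValueError(f"unknown baseline {which!r}; "
                         "expected naive_bayes, logistic or svm")
    model = Pipeline([("scale", StandardScaler()), ("clf", est)])
    model.fit(X, y)
    scorer = Scorer(name=which, model=model, positive_label=positive_label,
                    score_kind=kind)
    if kind == "decision":
        # orient the decision value toward the positive label
        classes = list(model.classes_)
        if classes.index(positive_label) == 0:
            inner = scorer.scores

            def flipped(X, _inner=inner):
                return -_inner(X)

            scorer.scores = flipped  # type: ignore[method-assign]
    return scorer


def train_classifier(name: str, train, y=None, seed: int = 0,
                     n_trees: int = DEFAULT_N_TREES,
                     positive_label=None) -> Scorer:
    """Dispatch by classifier name (see :data:`CLASSIFIERS`)."""
    if name == "ranking_forest":
        return train_ranking_forest(train, y, n_trees=n_trees, seed=seed,
                                    positive_label=positive_label)
    return train_baselines(train, y, which=name, seed=seed,
                           positive_label=positive_label)


# ---------------------------------------------------------------------------
# ROC evaluation

def _roc_counts(y_bin: np.ndarray, scores: np.ndarray):
    """Cumulative (fp, tp) integer counts at each distinct threshold."""
    order = np.argsort(-scores, kind="stable")
    ys = y_bin[order]
    ss = scores[order]
    last_of_block = np.r_[np.flatnonzero(np.diff(ss) != 0), ys.size - 1]
    tp = np.r_[0, np.cumsum(ys)[last_of_block]]
    fp = np.r_[0, np.cumsum(1 - ys)[last_of_block]]
    thresholds = np.r_[np.inf, ss[last_of_block]]
    return fp.astype(np.int64), tp.astype(np.int64), thresholds


@dataclass
class EvaluationResult:
    """ROC curve, AUC and Youden-point sensitivity/specificity.

    For cross-validated results the ROC/AUC fields describe the pooled
    out-of-fold scores while ``cv_*`` carry the per-fold values and their
    means (the headline CV numbers).
    """

    classifier: str
    auc: float
    sensitivity: float
    specificity: float
    roc: np.ndarray  # (k, 2) array of (FPR, TPR), (0,0) -> (1,1)
    threshold: float
    operating_rule: str = "youden-max (ties -> lower threshold)"
    feature_set: str | None = None
    condition: str | None = None
    seed: int | None = None
    cv_fold_auc: list[float] | None = None
    cv_fold_sensitivity: list[float] | None = None
    cv_fold_specificity: list[float] | None = None

    @property
    def cv_mean_auc(self) -> float | None:
        return float(np.mean(self.cv_fold_auc)) if self.cv_fold_auc else None

    @property
    def cv_mean_sensitivity(self) -> float | None:
        vals = self.cv_fold_sensitivity
        return float(np.mean(vals)) if vals else None

    @property
    def cv_mean_specificity(self) -> float | None:
        vals = self.cv_fold_specificity
        return float(np.mean(vals)) if vals else None

    def to_dict(self) -> dict:
        d = {
            "classifier": self.classifier,
            "feature_set": self.feature_set,
            "condition": self.condition,
            "auc": self.auc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "threshold": self.threshold,
            "operating_rule": self.operating_rule,
            "seed": self.seed,
        }
        if self.cv_fold_auc is not None:
            d.update({
                "cv_mean_auc": self.cv_mean_auc,
                "cv_mean_sensitivity": self.cv_mean_sensitivity,
                "cv_mean_specificity": self.cv_mean_specificity,
                "cv_fold_auc": self.cv_fold_auc,
                "cv_fold_sensitivity": self.cv_fold_sensitivity,
                "cv_fold_specificity": self.cv_fold_specificity,
            })
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def roc_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.roc, columns=["fpr", "tpr"]).to_csv(path, index=False)


def _evaluate_scores(y, scores, positive_label) -> tuple:
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    y_bin = (y == positive_label).astype(np.int64)
    n_pos = int(y_bin.sum())
    n_neg = int(y_bin.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("test set must contain both classes")
    fp, tp, thresholds = _roc_counts(y_bin, scores)
    # exact rational AUC: integer trapezoid numerator over 2 * n_pos * n_neg
    numerator = int(np.sum((fp[1:] - fp[:-1]) * (tp[1:] + tp[:-1])))
    auc = numerator / (2 * n_neg * n_pos)
    fpr = fp / n_neg
    tpr = tp / n_pos
    j = tpr - fpr
    idx = int(np.flatnonzero(j == j.max())[-1])  # ties -> lower threshold
    roc = np.column_stack([fpr, tpr])
    return auc, float(tpr[idx]), 1.0 - float(fpr[idx]), roc, float(thresholds[idx])


def evaluate(scorer: Scorer, test, y=None) -> EvaluationResult:
    """ROC evaluation of a fitted scorer on a test set.

    AUC is the exact trapezoidal area under the full ROC — identical to the
    Mann-Whitney pairwise-ordering statistic with tied scores counted half.
    Sensitivity/specificity are read at the Youden-optimal threshold.
    """
    X, y, _ = _as_xy(test, y, scorer.positive_label)
    if X.shape[0] == 0:
        raise EvaluationError("empty test set")
    scores = scorer.scores(X)
    auc, sen, spc, roc, thr = _evaluate_scores(y, scores, scorer.positive_label)
    return EvaluationResult(classifier=scorer.name, auc=auc, sensitivity=sen,
                            specificity=spc, roc=roc, threshold=thr)


def cross_validate(table, y=None, classifier: str = "ranking_forest",
                   k: int = 10, seed: int = 0,
                   n_trees: int = DEFAULT_N_TREES,
                   positive_label=None) -> EvaluationResult:
    """Stratified k-fold cross-validation of one classifier.

    Models are retrained per fold (scaling fit on the fold's training part
    only) and evaluated on the held-out part; the result carries per-fold
    AUC/sensitivity/specificity, their means, and a pooled-score ROC.
    """
    if k < 2:
        raise EvaluationError("k must be >= 2")
    X, y, positive_label = _as_xy(table, y, positive_label)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise EvaluationError(
            f"smallest class has {counts.min()} samples < k = {k}; lower k"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_auc, fold_sen, fold_spc = [], [], []
    pooled_scores = np.empty(y.shape[0], dtype=float)
    for tr_idx, te_idx in skf.split(X, y):
        scorer = train_classifier(classifier, X[tr_idx], y[tr_idx],
                                  seed=seed, n_trees=n_trees,
                                  positive_label=positive_label)
        scores = scorer.scores(X[te_idx])
        auc, sen, spc, _, _ = _evaluate_scores(y[te_idx], scores,
                                               positive_label)
        fold_auc.append(float(auc))
        fold_sen.append(float(sen))
        fold_spc.append(float(spc))
        pooled_scores[te_idx] = scores
    auc, sen, spc, roc, thr = _evaluate_scores(y, pooled_scores, positive_label)
    return EvaluationResult(
        classifier=classifier, auc=auc, sensitivity=sen, specificity=spc,
        roc=roc, threshold=thr, seed=seed,
        cv_fold_auc=fold_auc, cv_fold_sensitivity=fold_sen,
        cv_fold_specificity=fold_spc,
    )
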