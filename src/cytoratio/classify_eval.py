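"""Stratified cross-validated classification with AUC/sensitivity/specificity.

Five model families are evaluated: k-nearest neighbours, naive Bayes,
random forest, support vector machine and decision tree.  The naive Bayes
model is the pipeline's own: categorical naive Bayes over MDL-discretized
features with add-λ smoothing, so that its posterior decomposes exactly into
the additive log-odds points of the nomogram.  The other families delegate
to scikit-learn with default hyperparameters.

Metrics are computed on predictions pooled across the test folds (every
sample is tested exactly once): AUC from the pooled positive-class scores,
sensitivity and specificity from hard argmax decisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .fcbf import discretize, fcbf_select, mdl_discretize

MODEL_IDS = ("knn", "naive_bayes", "random_forest", "svm", "decision_tree")


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k−1 per sample).

    Fold sizes differ by at most one and per-fold class proportions are as
    close as the arithmetic allows.  A class smaller than ``k`` triggers a
    warning (folds then balance as closely as possible); a single class is
    an error since no model can be trained.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples {n}")
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("single-class labels: stratification undefined")
    if counts.min() < k:
        warnings.warn(
            f"class {classes[np.argmin(counts)]!r} has fewer than k={k} "
            "members; folds balance as closely as possible", stacklevel=2)
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            splits = splitter.split(np.zeros(n), labels)
            folds = np.empty(n, dtype=int)
            for f, (_, test) in enumerate(splits):
                folds[test] = f
        return folds
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(splitter.split(np.zeros(n), labels)):
        folds[test] = f
    return folds


# ---------------------------------------------------------------------------
# Discretized naive Bayes
# ---------------------------------------------------------------------------


@dataclass
class NBModel:
    """Categorical naive Bayes over discretized features.

    ``cond[f]`` holds the add-λ-smoothed P(bin | class) table of feature
    ``f`` (bins × classes, columns summing to 1); ``cuts[f]`` are the bin
    boundaries, so the model carries its own discretization.
    """

    classes: np.ndarray
    priors: np.ndarray
    features: list[str]
    cuts: dict[str, np.ndarray]
    cond: dict[str, np.ndarray]
    laplace: float = 1.0
    _class_index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._class_index = {c: i for i, c in enumerate(self.classes)}

    def _bin_codes(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        return {f: discretize(X[f].to_numpy(dtype=float), self.cuts[f])
                for f in self.features}

    def predict_log_proba(self, X: pd.DataFrame) -> np.ndarray:
        log_post = np.tile(np.log(self.priors), (len(X), 1))
        for f, codes in self._bin_codes(X).items():
            log_post += np.log(self.cond[f][codes, :])
        log_post -= log_post.max(axis=1, keepdims=True)
        p = np.exp(log_post)
        return np.log(p / p.sum(axis=1, keepdims=True))

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return np.exp(self.predict_log_proba(X))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.classes[np.argmax(self.predict_log_proba(X), axis=1)]

    def prior_log_odds(self, positive) -> float:
        """ln P(positive)/P(not positive) from the class priors."""
        i = self._class_index[positive]
        return float(np.log(self.priors[i]) - np.log(1.0 - self.priors[i]))

    def posterior_log_odds(self, X: pd.DataFrame, positive) -> np.ndarray:
        """ln posterior odds of the positive class (binary models only)."""
        if self.classes.size != 2:
            raise ValueError("posterior log odds require a binary model")
        lp = self.predict_log_proba(X)
        i = self._class_index[positive]
        return lp[:, i] - lp[:, 1 - i]


def nb_fit(features: pd.DataFrame, labels,
           cuts: dict[str, np.ndarray] | None = None,
           laplace: float = 1.0) -> NBModel:
    """Fit the discretized naive Bayes model.

    When ``cuts`` is omitted every feature is MDL-discretized against the
    labels (features with no accepted split collapse to a single
    uninformative bin).  Conditionals use add-λ smoothing, so every bin has
    strictly positive probability under every class.
    """
    if features.shape[1] == 0:
        raise ValueError("nb_fit requires at least one feature")
    labels = np.asarray(labels)
    classes, y = np.unique(labels, return_inverse=True)
    if classes.size < 2:
        raise ValueError("nb_fit requires at least two classes")
    priors = np.bincount(y).astype(float) / y.size

    if cuts is None:
        cuts = {f: mdl_discretize(features[f].to_numpy(dtype=float), labels)
                for f in features.columns}
    cond: dict[str, np.ndarray] = {}
    for f in features.columns:
        codes = discretize(features[f].to_numpy(dtype=float), cuts[f])
        n_bins = len(cuts[f]) + 1
        counts = np.zeros((n_bins, classes.size))
        np.add.at(counts, (codes, y), 1.0)
        cond[f] = (counts + laplace) / (
            counts.sum(axis=0, keepdims=True) + laplace * n_bins)
    return NBModel(classes=classes, priors=priors,
                   features=list(features.columns), cuts=dict(cuts),
                   cond=cond, laplace=laplace)


# ---------------------------------------------------------------------------
# Cross-validated evaluation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVResult:
    """Pooled out-of-fold performance of one model family."""

    model: str
    auc: float
    sensitivity: float
    specificity: float
    folds: np.ndarray
    seed: int
    positive: object


def _sklearn_model(model_id: str, seed: int):
    if model_id == "knn":
        return KNeighborsClassifier()
    if model_id == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if model_id == "svm":
        return SVC(random_state=seed)
    if model_id == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    raise ValueError(f"unknown model id {model_id!r}")


def _positive_scores(model, X: np.ndarray, positive) -> np.ndarray:
    """Positive-class score for pooled-AUC ranking."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        j = list(model.classes_).index(positive)
        return proba[:, j]
    df = model.decision_function(X)
    return df if model.classes_[1] == positive else -df


def evaluate(features: pd.DataFrame, labels, model_id: str,
             folds: np.ndarray, positive, seed: int = 0,
             nested_select: bool = False,
             pooled: bool = True) -> CVResult:
    """Cross-validated evaluation with pooled out-of-fold metrics.

    Parameters
    ----------
    features
        Samples × features matrix (already feature-selected when emulating
        the full-dataset selection protocol).
    nested_select
        Run FCBF inside each training fold and evaluate only the selected
        features — the leakage-free variant of the protocol.  When a fold
        selects nothing, the model falls back to the training-fold prior.
    pooled
        Pool out-of-fold scores for a single AUC (default); otherwise
        average per-fold AUCs.

    Notes
    -----
    Sensitivity = TP/(TP+FN) and specificity = TN/(TN+FP) are always from
    pooled hard argmax decisions with ``positive`` as the positive class.
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model id {model_id!r}; "
                         f"expected one of {MODEL_IDS}")
    labels = np.asarray(labels)
    folds = np.asarray(folds)
    y_bin = labels == positive
    if not y_bin.any() or y_bin.all():
        raise ValueError(f"positive class {positive!r} must be a proper "
                         "subset of the labels")

    scores = np.full(len(labels), np.nan)
    preds = np.empty(len(labels), dtype=object)
    fold_aucs = []
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        y_train = labels[train]
        if np.unique(y_train).size < 2:
            warnings.warn(f"fold {f} has single-class training data; skipped",
                          stacklevel=2)
            continue

        X_train, X_test = features.loc[train], features.loc[test]
        if nested_select:
            sel = [s.feature for s in fcbf_select(X_train, y_train)
                   if s.selected]
            if not sel:
                # Nothing informative in this training fold: prior fallback.
                p_pos = float((y_train == positive).mean())
                scores[test] = p_pos
                majority = pd.Series(y_train).mode().iloc[0]
                preds[test] = majority
                fold_aucs.append(0.5)
                continue
            X_train, X_test = X_train[sel], X_test[sel]

        if model_id == "naive_bayes":
            model = nb_fit(X_train, y_train)
            proba = model.predict_proba(X_test)
            j = list(model.classes).index(positive)
            s = proba[:, j]
            p = model.predict(X_test)
        else:
            model = _sklearn_model(model_id, seed)
            model.fit(X_train.to_numpy(dtype=float), y_train)
            s = _positive_scores(model, X_test.to_numpy(dtype=float),
                                 positive)
            p = model.predict(X_test.to_numpy(dtype=float))
        scores[test] = s
        preds[test] = p
        if y_bin[test].any() and not y_bin[test].all() and np.ptp(s) > 0:
            fold_aucs.append(float(roc_auc_score(y_bin[test], s)))
        elif y_bin[test].any() and not y_bin[test].all():
            fold_aucs.append(0.5)

    tested = ~pd.isna(scores)
    if pooled:
        auc = float(roc_auc_score(y_bin[tested], scores[tested])) \
            if np.ptp(scores[tested]) > 0 else 0.5
    else:
        auc = float(np.mean(fold_aucs)) if fold_aucs else float("nan")

    pred_pos = np.array([p == positive for p in preds[tested]])
    actual_pos = y_bin[tested]
    tp = int((pred_pos & actual_pos).sum())
    fn = int((~pred_pos & actual_pos).sum())
    tn = int((~pred_pos & ~actual_pos).sum())
    fp = int((pred_pos & ~actual_pos).sum())
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return CVResult(model=model_id, auc=auc, sensitivity=sens,
                    specificity=spec, folds=folds, seed=seed,
                    positive=positive)


def evaluate_all(features: pd.DataFrame, labels, positive, k: int = 5,
                 seed: int = 0, models: tuple[str, ...] = MODEL_IDS,
                 nested_select: bool = False) -> pd.DataFrame:
    """Evaluate several model families on shared folds; one row per model."""
    folds = stratified_kfold(labels, k=k, seed=seed)
    rows = []
    for m in models:
        r = evaluate(features, labels, m, folds, positive, seed=seed,
                     nested_select=nested_select)
        rows.append({"model": m, "auc": r.auc, "sensitivity": r.sensitivity,
                     "specificity": r.specificity})
    return pd.DataFrame(rows).set_index("model")
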