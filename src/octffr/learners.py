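"""Univariate base learners under grouped cross-validation.

Each feature is modeled on its own by every algorithm in a fixed registry
of 12 base learners.  Two evaluation protocols are provided:

* a tenfold patient-grouped, label-stratified cross-validation repeated
  over 10 seeds, used to rank features by mean accuracy;
* leave-one-patient-out (one fold per patient, all lesions of the held-out
  patient in the test set), used to produce the out-of-fold class
  probabilities and crisp labels that feed the ensemble.

In both protocols the decision threshold is chosen per fold on the
training set so as to balance sensitivity and specificity, and only then
applied to the held-out lesions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneGroupOut, StratifiedGroupKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier


@dataclass(frozen=True)
class AlgorithmSpec:
    """A registered base learner: name, hyperparameters and seed."""

    name: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.name not in ALGORITHM_REGISTRY:
            raise ValueError(f"unknown algorithm {self.name!r}; "
                             f"registered: {list(ALGORITHM_REGISTRY)}")

    def build(self):
        return ALGORITHM_REGISTRY[self.name](self.seed, **self.params)


def _scaled(estimator):
    """Per-fold column standardization in front of the estimator.

    The feature matrix arrives L1-normalized, which puts columns on a
    ~1/n scale; re-standardizing inside each training fold keeps the
    regularized and kernel learners scale-robust without leaking test
    statistics.  For a single feature this is a monotone affine map, so
    ranks, neighbors and thresholds are unaffected.
    """
    return make_pipeline(StandardScaler(), estimator)


#: The 12 base learners: SVMs with linear / cubic-polynomial / RBF("scale")
#: kernels, a decision tree, 5-nearest neighbors, random forests with
#: 20/40/60/100 trees, AdaBoost, Gaussian naive Bayes and logistic
#: regression.  Registry order is the deterministic tie-break order.
def _platt_svc(**kwargs):
    # cross-validated Platt scaling supplies the SVM class probabilities
    return CalibratedClassifierCV(SVC(**kwargs), ensemble=False)


ALGORITHM_REGISTRY = {
    "svm_linear": lambda seed: _scaled(_platt_svc(kernel="linear",
                                                  random_state=seed)),
    "svm_poly": lambda seed, degree=3: _scaled(_platt_svc(
        kernel="poly", degree=degree, random_state=seed)),
    "svm_rbf": lambda seed: _scaled(_platt_svc(kernel="rbf", gamma="scale",
                                               random_state=seed)),
    "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
    "knn": lambda seed, k=5: _scaled(KNeighborsClassifier(n_neighbors=k)),
    "random_forest_20": lambda seed: RandomForestClassifier(
        n_estimators=20, random_state=seed),
    "random_forest_40": lambda seed: RandomForestClassifier(
        n_estimators=40, random_state=seed),
    "random_forest_60": lambda seed: RandomForestClassifier(
        n_estimators=60, random_state=seed),
    "random_forest_100": lambda seed: RandomForestClassifier(
        n_estimators=100, random_state=seed),
    "adaboost": lambda seed: AdaBoostClassifier(random_state=seed),
    "naive_bayes": lambda seed: GaussianNB(),
    "logistic_regression": lambda seed: _scaled(LogisticRegression(
        max_iter=2000, random_state=seed)),
}


@dataclass(frozen=True)
class AccuracySummary:
    """Per-seed accuracies (%) of one feature/algorithm pair."""

    feature: str
    algorithm: str
    accuracies: tuple   # one pooled accuracy per seed, percent

    @property
    def mean(self):
        return float(np.mean(self.accuracies))

    @property
    def sd(self):
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0

    @property
    def max(self):
        return float(np.max(self.accuracies))

    @property
    def min(self):
        return float(np.min(self.accuracies))


@dataclass
class ModelOutput:
    """Out-of-fold outputs of one univariate (or multivariate) model."""

    feature: str
    algorithm: str
    lesion_ids: np.ndarray
    prob: np.ndarray       # O_i: out-of-fold class probability, [0, 1]
    crisp: np.ndarray      # C_i: out-of-fold crisp label, {0, 1} (NaN if skipped)
    accuracy: float        # pooled out-of-fold accuracy (fraction)
    n_skipped_folds: int = 0


def balance_threshold(scores, labels) -> float:
    """Threshold minimizing |Se - Sp| on the given (training) set.

    Candidates are the midpoints between consecutive sorted unique scores
    plus ±inf sentinels; positive call is ``score >= threshold``.  Ties are
    broken by maximal Se + Sp, then by the smallest threshold.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present to balance Se and Sp")
    scores = np.asarray(scores, dtype=float)
    from octffr.roc import candidate_thresholds
    n_pos = labels.sum()
    n_neg = len(labels) - n_pos
    best = None
    for t in candidate_thresholds(scores):
        called = scores >= t
        se = (called & (labels == 1)).sum() / n_pos
        sp = (~called & (labels == 0)).sum() / n_neg
        key = (abs(se - sp), -(se + sp), t)
        if best is None or key < best[0]:
            best = (key, t)
    return float(best[1])


def _fold_scores(model, X, calibrator=None):
    scores = model.predict_proba(X)[:, 1]
    if calibrator is not None:
        scores = calibrator.predict(scores)
    return scores


def lopo_predictions(features: pd.DataFrame,
                     labels,
                     groups,
                     algorithm: AlgorithmSpec,
                     columns=None,
                     calibrate: bool = False) -> ModelOutput:
    """Leave-one-patient-out out-of-fold predictions.

    One fold per patient: the model is fit on all other patients' lesions,
    the Se/Sp-balancing threshold is chosen on the training predictions,
    and the held-out lesions receive the model's class probability (O_i)
    and the thresholded crisp label (C_i).  A training fold missing one of
    the classes is skipped with a warning and its lesions left NaN.

    ``columns`` selects the feature column(s); a single column gives a
    univariate model, several give the multivariate baseline.
    """
    if columns is None:
        columns = list(features.columns)
    elif isinstance(columns, str):
        columns = [columns]
    X = features[columns].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("leave-one-patient-out needs at least 2 patients")

    prob = np.full(len(y), np.nan)
    crisp = np.full(len(y), np.nan)
    n_skipped = 0
    for train, test in LeaveOneGroupOut().split(X, y, groups):
        if len(np.unique(y[train])) < 2:
            warnings.warn(
                f"fold for patient {groups[test][0]!r} skipped: "
                "single-class training labels", stacklevel=2)
            n_skipped += 1
            continue
        model = algorithm.build()
        model.fit(X[train], y[train])
        calibrator = None
        train_scores = model.predict_proba(X[train])[:, 1]
        if calibrate:
            calibrator = IsotonicRegression(out_of_bounds="clip")
            calibrator.fit(train_scores, y[train])
            train_scores = calibrator.predict(train_scores)
        thr = balance_threshold(train_scores, y[train])
        test_scores = _fold_scores(model, X[test], calibrator)
        prob[test] = test_scores
        crisp[test] = (test_scores >= thr).astype(float)
    valid = ~np.isnan(crisp)
    accuracy = float((crisp[valid] == y[valid]).mean()) if valid.any() else np.nan
    return ModelOutput(
        feature="+".join(columns),
        algorithm=algorithm.name,
        lesion_ids=np.asarray(features.index),
        prob=prob,
        crisp=crisp,
        accuracy=accuracy,
        n_skipped_folds=n_skipped,
    )


def tenfold_accuracy_study(features: pd.DataFrame,
                           labels,
                           groups,
                           feature_name: str,
                           algorithm_name: str,
                           n_seeds: int = 10,
                           n_folds: int = 10) -> AccuracySummary:
    """Repeated stratified patient-grouped tenfold CV for one feature/algorithm.

    For each seed the folds are re-drawn (stratified by label at the
    patient-group level) and the learner is re-seeded; the per-seed
    accuracy pools the per-fold predictions obtained with each fold's
    Se/Sp-balanced training threshold.
    """
    X = features[[feature_name]].to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    groups = np.asarray(groups)
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    if len(np.unique(groups)) < n_folds:
        raise ValueError(f"need at least {n_folds} patients for {n_folds}-fold CV")

    per_seed = []
    for seed in range(n_seeds):
        spec = AlgorithmSpec(algorithm_name, seed=seed)
        cv = StratifiedGroupKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        pred = np.full(len(y), np.nan)
        for train, test in cv.split(X, y, groups):
            if len(np.unique(y[train])) < 2:
                continue
            model = spec.build()
            model.fit(X[train], y[train])
            thr = balance_threshold(model.predict_proba(X[train])[:, 1], y[train])
            pred[test] = (model.predict_proba(X[test])[:, 1] >= thr).astype(float)
        valid = ~np.isnan(pred)
        per_seed.append(100.0 * float((pred[valid] == y[valid]).mean()))
    return AccuracySummary(feature=feature_name, algorithm=algorithm_name,
                           accuracies=tuple(per_seed))


def select_best_algorithm(summaries) -> AccuracySummary:
    """Highest mean accuracy; ties broken by lower sd, then registry order."""
    summaries = list(summaries)
    if not summaries:
        raise ValueError("no summaries to select from")
    order = list(ALGORITHM_REGISTRY)
    return min(summaries,
               key=lambda s: (-s.mean, s.sd, order.index(s.algorithm)))


def rank_features(best_per_feature, min_mean_acc: float = 60.0,
                  order: str | list = "accuracy"):
    """Keep features whose mean accuracy meets the cutoff, in rank order.

    ``order='accuracy'`` sorts by descending mean accuracy (synthetic-data
    default); a list fixes an external rank (e.g. the study's printed
    feature order) and filters it by the cutoff.
    """
    by_name = {s.feature: s for s in best_per_feature}
    if isinstance(order, str):
        if order != "accuracy":
            raise ValueError("order must be 'accuracy' or an explicit list")
        kept = [s.feature for s in sorted(
            by_name.values(), key=lambda s: (-s.mean, s.sd, s.feature))
            if s.mean >= min_mean_acc]
    else:
        kept = [name for name in order
                if name in by_name and by_name[name].mean >= min_mean_acc]
    return kept
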