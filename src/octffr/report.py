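"""Diagnostic reporting: confusion-matrix metrics, confidence intervals,
zone and clinical-subgroup breakdowns, and the multivariate baseline.

Percentages are reported to two decimals, AUCs to three.  Proportion CIs
use the Wilson score interval; AUC CIs use the Hanley–McNeil closed-form
standard error by default (a stratified bootstrap is available behind a
flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from octffr.learners import AlgorithmSpec, lopo_predictions


@dataclass(frozen=True)
class ConfusionMatrix:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one case")

    @property
    def total(self):
        return self.TP + self.TN + self.FP + self.FN

    @classmethod
    def from_predictions(cls, predictions, labels) -> "ConfusionMatrix":
        p = np.asarray(predictions, dtype=int)
        y = np.asarray(labels, dtype=int)
        if p.shape != y.shape:
            raise ValueError("predictions and labels must align")
        return cls(TP=int(((p == 1) & (y == 1)).sum()),
                   TN=int(((p == 0) & (y == 0)).sum()),
                   FP=int(((p == 1) & (y == 0)).sum()),
                   FN=int(((p == 0) & (y == 1)).sum()))


def diagnostic_metrics(cm: ConfusionMatrix) -> dict:
    """Accuracy, sensitivity, specificity, PPV and NPV in percent.

    A metric whose denominator is zero is reported as None (undefined),
    never as NaN.
    """
    def ratio(num, den):
        return 100.0 * num / den if den > 0 else None

    return {
        "accuracy": ratio(cm.TP + cm.TN, cm.total),
        "sensitivity": ratio(cm.TP, cm.TP + cm.FN),
        "specificity": ratio(cm.TN, cm.TN + cm.FP),
        "ppv": ratio(cm.TP, cm.TP + cm.FP),
        "npv": ratio(cm.TN, cm.TN + cm.FN),
    }


def wilson_ci(successes: int, n: int, level: float = 0.95):
    """Wilson score interval for a binomial proportion, in percent."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= successes <= n:
        raise ValueError("successes must lie in [0, n]")
    lo, hi = proportion_confint(successes, n, alpha=1 - level, method="wilson")
    return 100.0 * lo, 100.0 * hi


def auc_ci_hanley_mcneil(auc: float, n_pos: int, n_neg: int,
                         level: float = 0.95):
    """Hanley–McNeil confidence interval for an AUC.

    SE^2 = [A(1-A) + (n_pos-1)(Q1-A^2) + (n_neg-1)(Q2-A^2)] / (n_pos n_neg)
    with Q1 = A/(2-A) and Q2 = 2A^2/(1+A); the interval A ± z·SE is clamped
    to [0, 1].
    """
    if not 0.5 <= auc <= 1.0:
        raise ValueError("auc must lie in [0.5, 1]")
    if n_pos < 2 or n_neg < 2:
        raise ValueError("need at least 2 cases per class")
    from scipy.stats import norm
    z = norm.ppf(0.5 + level / 2.0)
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc * auc / (1.0 + auc)
    se = np.sqrt((auc * (1 - auc) + (n_pos - 1) * (q1 - auc ** 2)
                  + (n_neg - 1) * (q2 - auc ** 2)) / (n_pos * n_neg))
    return float(max(auc - z * se, 0.0)), float(min(auc + z * se, 1.0))


def auc_ci_bootstrap(scores, labels, level: float = 0.95,
                     n_boot: int = 2000, seed: int = 0):
    """Stratified-bootstrap percentile CI for an AUC (alternative method)."""
    from octffr.roc import auc_score
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos, neg = np.where(y == 1)[0], np.where(y == 0)[0]
    stats = []
    for _ in range(n_boot):
        idx = np.concatenate([rng.choice(pos, len(pos)), rng.choice(neg, len(neg))])
        stats.append(auc_score(scores[idx], y[idx]))
    alpha = (1 - level) / 2
    return (float(np.quantile(stats, alpha)),
            float(np.quantile(stats, 1 - alpha)))


def subgroup_report(predictions, labels, metadata: pd.DataFrame,
                    corrected_ffr=None,
                    gray_zone=(0.75, 0.83)) -> pd.DataFrame:
    """Accuracy per FFR zone and per clinical subgroup.

    ``metadata`` is the cohort table (one row per lesion, aligned with the
    predictions) with columns vessel, proximal_lad, sex, aht, diabetes.
    When ``corrected_ffr`` is given, accuracies inside vs outside the
    (inclusive) gray zone are reported as well.  Empty subgroups appear
    with n = 0 and no accuracy.
    """
    p = np.asarray(predictions, dtype=int)
    y = np.asarray(labels, dtype=int)
    correct = p == y
    rows = []

    def add(group, category, mask):
        n = int(mask.sum())
        rows.append({
            "group": group, "category": category, "n": n,
            "n_correct": int(correct[mask].sum()) if n else 0,
            "accuracy": 100.0 * correct[mask].mean() if n else None,
        })

    if corrected_ffr is not None:
        ffr = np.asarray(corrected_ffr, dtype=float)
        inside = (ffr >= gray_zone[0]) & (ffr <= gray_zone[1])
        add("ffr_zone", f"inside [{gray_zone[0]}, {gray_zone[1]}]", inside)
        add("ffr_zone", "outside", ~inside)
    for group, column in [("vessel", "vessel"), ("proximal_lad", "proximal_lad"),
                          ("sex", "sex"), ("hypertensive", "aht"),
                          ("diabetes", "diabetes")]:
        values = metadata[column].to_numpy()
        for cat in pd.unique(values):
            add(group, str(cat), values == cat)
    return pd.DataFrame(rows)


def multivariate_baseline(features: pd.DataFrame,
                          labels,
                          groups,
                          ranked_features,
                          ks=range(5, 14),
                          algorithm: str = "random_forest_60",
                          seed: int = 0) -> pd.DataFrame:
    """Single multivariate model on the top-k features under the same
    leave-one-patient-out protocol, for comparison with the ensemble."""
    y = np.asarray(labels, dtype=int)
    rows = []
    for k in ks:
        if k > len(ranked_features):
            raise ValueError(f"top-{k} exceeds the {len(ranked_features)} "
                             "ranked features")
        out = lopo_predictions(features, y, groups,
                               AlgorithmSpec(algorithm, seed=seed),
                               columns=list(ranked_features[:k]))
        valid = ~np.isnan(out.crisp)
        n_correct = int((out.crisp[valid] == y[valid]).sum())
        ci = wilson_ci(n_correct, int(valid.sum()))
        rows.append({"k": k, "algorithm": algorithm,
                     "accuracy": 100.0 * n_correct / valid.sum(),
                     "ci_low": ci[0], "ci_high": ci[1]})
    return pd.DataFrame(rows)
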