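"""ROC analysis with closest-to-(0,1) optimal-cutoff selection.

The positive-call convention throughout is ``score >= threshold``.  The
candidate thresholds are the midpoints between consecutive sorted unique
scores plus two sentinels (-inf: everything positive; +inf: nothing
positive), so every achievable confusion matrix appears exactly once on the
curve.  The optimal operating point is the one closest, in Euclidean
distance, to the perfect-classifier corner (FPR, TPR) = (0, 1) — the
criterion used here in preference to the Youden index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class RocCurve:
    """Ordered (threshold, sensitivity, specificity) triples.

    Thresholds increase; sensitivity is non-increasing along the curve and
    the sentinel endpoints (Se=1, Sp=0) and (Se=0, Sp=1) are always present.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def __len__(self):
        return len(self.thresholds)


def _check_two_classes(labels):
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return labels


def candidate_thresholds(scores) -> np.ndarray:
    """Midpoints between consecutive sorted unique scores, with ±inf sentinels."""
    uniq = np.unique(np.asarray(scores, dtype=float))
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def roc_points(scores, labels) -> RocCurve:
    """Exact ROC curve over all candidate thresholds."""
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    thresholds = candidate_thresholds(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    se = np.empty(len(thresholds))
    sp = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        called = scores >= t
        se[i] = (called & (labels == 1)).sum() / n_pos
        sp[i] = (~called & (labels == 0)).sum() / n_neg
    return RocCurve(thresholds=thresholds, sensitivity=se, specificity=sp)


def auc_score(scores, labels) -> float:
    """Mann–Whitney AUC: (concordant pairs + half the ties) / (n_pos * n_neg).

    Equals the trapezoidal area under the step ROC curve.
    """
    labels = _check_two_classes(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    ranks = rankdata(scores)   # midranks handle ties
    rank_sum_pos = ranks[labels == 1].sum()
    return float((rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def cutoff_closest_to_01(curve: RocCurve) -> float:
    """Threshold minimizing the distance to the (FPR, TPR) = (0, 1) corner.

    Minimizes sqrt((1-Se)^2 + (1-Sp)^2); ties broken by larger sensitivity,
    then by the smallest threshold.
    """
    d2 = (1.0 - curve.sensitivity) ** 2 + (1.0 - curve.specificity) ** 2
    best = 0
    for i in range(1, len(curve)):
        if d2[i] < d2[best] - 1e-15:
            best = i
        elif abs(d2[i] - d2[best]) <= 1e-15:
            if curve.sensitivity[i] > curve.sensitivity[best] + 1e-15:
                best = i
            # equal distance and Se: keep the earlier (smaller) threshold
    return float(curve.thresholds[best])
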