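"""Ensemble voting over univariate model outputs.

Each univariate model contributes one binary vote per lesion.  Three
strategies turn the out-of-fold outputs into votes:

* M1 — every model's probability is compared to the *mean* of the
  closest-to-(0,1) ROC cutoffs of all models;
* M2 — every model's probability is compared to its *own* ROC cutoff;
* M3 — the votes are the models' crisp labels (the per-fold-thresholded
  decisions); the ROC cutoff of the mean crisp vote is computed and
  reported for completeness (it is degenerate by construction).

Votes are combined by simple majority or by accuracy-weighted voting with
log-odds weights w_i = ln(acc_i / (1 - acc_i)); the weighted score is
normalized by the weight sum so that the 0.5 comparison (and hence the
final label) is invariant to the logarithm base and to positive rescaling
of the weights.  A score of exactly 0.5 is called positive, erring toward
detecting significant lesions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from octffr.learners import ModelOutput
from octffr.roc import auc_score, cutoff_closest_to_01, roc_points

STRATEGIES = ("M1", "M2", "M3")


@dataclass(frozen=True)
class EnsembleConfig:
    strategy: str = "M3"
    voting: str = "weighted"
    top_k: int = 5
    weight_epsilon: float = 1e-6

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if self.voting not in ("simple", "weighted"):
            raise ValueError("voting must be 'simple' or 'weighted'")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 < self.weight_epsilon < 0.5:
            raise ValueError("weight_epsilon must lie in (0, 0.5)")


@dataclass
class EnsemblePrediction:
    lesion_ids: np.ndarray
    votes: np.ndarray        # (n_models, n_lesions) binary
    score: np.ndarray        # [0, 1] per lesion
    label: np.ndarray        # {0, 1} per lesion; score >= 0.5 is positive
    weights: np.ndarray
    cutoffs: dict            # per-model / mean ROC cutoffs used


def weight_from_accuracy(acc: float, epsilon: float = 1e-6) -> float:
    """Log-odds voting weight w = ln(acc / (1 - acc)), with acc clipped to
    [epsilon, 1 - epsilon]; negative for below-chance models."""
    a = float(np.clip(acc, epsilon, 1.0 - epsilon))
    return float(np.log(a / (1.0 - a)))


def _check_aligned(outputs):
    ids = outputs[0].lesion_ids
    for out in outputs[1:]:
        if len(out.lesion_ids) != len(ids) or np.any(out.lesion_ids != ids):
            raise ValueError("model outputs cover mismatched lesion sets")
    for out in outputs:
        if np.isnan(out.prob).any() or np.isnan(out.crisp).any():
            raise ValueError(
                f"model {out.feature}/{out.algorithm} has unscored lesions "
                "(skipped folds); drop them before voting")
    return ids


def make_votes(outputs: list[ModelOutput], strategy: str, labels):
    """Per-model binary votes under aggregation strategy M1/M2/M3.

    Returns ``(votes, cutoffs)`` where ``votes`` is (n_models, n_lesions)
    and ``cutoffs`` records the ROC thresholds involved.
    """
    if not outputs:
        raise ValueError("need at least one model output")
    if strategy not in STRATEGIES:
        raise ValueError(f"strategy must be one of {STRATEGIES}")
    ids = _check_aligned(outputs)
    y = np.asarray(labels, dtype=int)

    if strategy in ("M1", "M2"):
        taus = np.array([
            cutoff_closest_to_01(roc_points(out.prob, y)) for out in outputs])
        if strategy == "M1":
            tau_bar = float(np.mean(taus))
            votes = np.stack([(out.prob >= tau_bar).astype(int) for out in outputs])
            cutoffs = {"per_model": taus, "mean": tau_bar}
        else:
            votes = np.stack([
                (out.prob >= tau).astype(int) for out, tau in zip(outputs, taus)])
            cutoffs = {"per_model": taus}
    else:  # M3: votes are the crisp labels; report the ROC cutoff on their mean
        votes = np.stack([out.crisp.astype(int) for out in outputs])
        mean_crisp = votes.mean(axis=0)
        if y.min() != y.max() and len(np.unique(mean_crisp)) > 1:
            crisp_cutoff = cutoff_closest_to_01(roc_points(mean_crisp, y))
        else:
            crisp_cutoff = np.nan
        cutoffs = {"crisp_mean_cutoff": crisp_cutoff}
    return votes, cutoffs


def aggregate_votes(votes: np.ndarray,
                    voting: str = "simple",
                    accuracies=None,
                    lesion_ids=None,
                    cutoffs=None,
                    weight_epsilon: float = 1e-6) -> EnsemblePrediction:
    """Combine binary votes into an ensemble score and final label.

    Simple voting averages the votes; weighted voting uses normalized
    log-odds weights, so the final label never changes under a positive
    rescaling of all weights.  If the weight sum is non-positive (all
    models at or below chance) an error advises simple voting instead.
    """
    votes = np.asarray(votes)
    if not np.isin(votes, (0, 1)).all():
        raise ValueError("votes must be binary")
    n_models = votes.shape[0]
    if voting == "simple":
        weights = np.ones(n_models)
    elif voting == "weighted":
        if accuracies is None or len(accuracies) != n_models:
            raise ValueError("weighted voting needs one accuracy per model")
        weights = np.array([weight_from_accuracy(a, weight_epsilon)
                            for a in accuracies])
        if weights.sum() <= 0:
            raise ValueError(
                "non-positive weight sum (all models at or below chance); "
                "use simple voting instead")
    else:
        raise ValueError("voting must be 'simple' or 'weighted'")
    score = weights @ votes / weights.sum()
    label = (score >= 0.5).astype(int)
    if lesion_ids is None:
        lesion_ids = np.arange(votes.shape[1])
    return EnsemblePrediction(lesion_ids=np.asarray(lesion_ids), votes=votes,
                              score=score, label=label, weights=weights,
                              cutoffs=cutoffs or {})


def run_topk_sweep(outputs_ranked: list[ModelOutput],
                   labels,
                   strategies=STRATEGIES,
                   voting: str = "weighted",
                   k_max: int | None = None,
                   weight_epsilon: float = 1e-6) -> pd.DataFrame:
    """Ensemble accuracy and AUC for every top-k prefix of the ranked models.

    For each k = 1..k_max and each strategy, the top-k univariate models
    vote and the aggregated prediction is scored against the labels:
    accuracy with its Wilson 95% CI, the AUC of the ensemble vote score
    ("crisp") and of the mean class probability, each with a Hanley–McNeil
    95% CI.
    """
    from octffr.report import auc_ci_hanley_mcneil, wilson_ci

    y = np.asarray(labels, dtype=int)
    if k_max is None:
        k_max = len(outputs_ranked)
    if k_max > len(outputs_ranked):
        raise ValueError(f"k_max={k_max} exceeds the {len(outputs_ranked)} "
                         "available models")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    rows = []
    for k in range(1, k_max + 1):
        subset = outputs_ranked[:k]
        accs = [out.accuracy for out in subset]
        mean_prob = np.mean([out.prob for out in subset], axis=0)
        for strategy in strategies:
            votes, cutoffs = make_votes(subset, strategy, y)
            pred = aggregate_votes(votes, voting=voting, accuracies=accs,
                                   weight_epsilon=weight_epsilon)
            n_correct = int((pred.label == y).sum())
            acc = 100.0 * n_correct / len(y)
            ci_lo, ci_hi = wilson_ci(n_correct, len(y))
            auc_crisp = auc_score(pred.score, y)
            auc_prob = auc_score(mean_prob, y)
            crisp_ci = auc_ci_hanley_mcneil(max(auc_crisp, 0.5), n_pos, n_neg)
            prob_ci = auc_ci_hanley_mcneil(max(auc_prob, 0.5), n_pos, n_neg)
            rows.append({
                "strategy": strategy, "voting": voting, "k": k,
                "accuracy": acc, "ci_low": ci_lo, "ci_high": ci_hi,
                "auc_crisp": auc_crisp,
                "auc_crisp_ci_low": crisp_ci[0], "auc_crisp_ci_high": crisp_ci[1],
                "auc_prob": auc_prob,
                "auc_prob_ci_low": prob_ci[0], "auc_prob_ci_high": prob_ci[1],
            })
    return pd.DataFrame(rows)
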