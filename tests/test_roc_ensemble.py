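"""ROC construction, optimal cutoffs, log-odds weights and voting."""

import numpy as np
import pytest

from conftest import brute_force_auc
from octffr.ensemble import (
    EnsembleConfig,
    aggregate_votes,
    make_votes,
    run_topk_sweep,
    weight_from_accuracy,
)
from octffr.learners import ModelOutput
from octffr.roc import auc_score, cutoff_closest_to_01, roc_points


def mk_output(prob, crisp=None, acc=0.8, name="m"):
    prob = np.asarray(prob, float)
    crisp = (prob >= 0.5).astype(float) if crisp is None else np.asarray(crisp, float)
    return ModelOutput(feature=name, algorithm="x",
                       lesion_ids=np.arange(len(prob)), prob=prob,
                       crisp=crisp, accuracy=acc)


class TestRocAndAuc:
    def test_worked_four_point_set(self):
        """pos {0.9, 0.4}, neg {0.6, 0.1}: 3 of 4 pairs concordant."""
        scores = [0.9, 0.4, 0.6, 0.1]
        labels = [1, 1, 0, 0]
        assert auc_score(scores, labels) == pytest.approx(0.75)
        curve = roc_points(scores, labels)
        # thresholds: -inf, .25, .5, .75, inf — enumerate Se/Sp by hand
        assert list(curve.sensitivity) == pytest.approx([1, 1, 0.5, 0.5, 0])
        assert list(curve.specificity) == pytest.approx([0, 0.5, 0.5, 1, 1])

    def test_perfect_and_flipped(self):
        labels = [1, 1, 0, 0]
        assert auc_score([0.9, 0.8, 0.2, 0.1], labels) == 1.0
        assert auc_score([0.9, 0.8, 0.2, 0.1], [0, 0, 1, 1]) == 0.0
        curve = roc_points([0.9, 0.8, 0.2, 0.1], labels)
        perfect = (curve.sensitivity == 1) & (curve.specificity == 1)
        assert perfect.any()

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(0)
        scores = rng.uniform(size=4000)
        labels = rng.integers(0, 2, 4000)
        assert abs(auc_score(scores, labels) - 0.5) < 0.03

    def test_brute_force_pair_counting_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(60):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.uniform(size=n), 1)   # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert auc_score(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        base = auc_score(scores, labels)
        for f in (np.exp, np.tanh, lambda s: 3 * s - 7):
            assert auc_score(f(scores), labels) == pytest.approx(base, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc_score([0.1, 0.9], [1, 1])


class TestOptimalCutoff:
    def test_perfect_classifier_has_zero_distance(self):
        curve = roc_points([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        t = cutoff_closest_to_01(curve)
        i = list(curve.thresholds).index(t)
        assert curve.sensitivity[i] == curve.specificity[i] == 1.0

    def test_exhaustive_scan_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(60):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.uniform(size=n), 1)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            curve = roc_points(scores, labels)
            d2 = (1 - curve.sensitivity) ** 2 + (1 - curve.specificity) ** 2
            keys = list(zip(d2, -curve.sensitivity, curve.thresholds))
            assert cutoff_closest_to_01(curve) == min(keys)[2]

    def test_differs_from_youden_on_constructed_curve(self):
        """A curve where Youden's J and the distance criterion disagree."""
        scores = [0.95, 0.9, 0.85, 0.6, 0.55, 0.5, 0.45, 0.1]
        labels = [1, 1, 1, 1, 0, 1, 0, 0]
        curve = roc_points(scores, labels)
        youden = curve.thresholds[np.argmax(curve.sensitivity
                                            + curve.specificity - 1)]
        closest = cutoff_closest_to_01(curve)
        d2 = lambda t: min((1 - se) ** 2 + (1 - sp) ** 2
                           for th, se, sp in zip(curve.thresholds,
                                                 curve.sensitivity,
                                                 curve.specificity)
                           if th == t)
        assert d2(closest) <= d2(youden)


class TestWeights:
    @pytest.mark.parametrize("acc, w", [
        (0.5, 0.0),
        (0.6735, 0.7241),   # ln(0.6735/0.3265)
        (0.25, np.log(1 / 3)),
    ])
    def test_log_odds_values(self, acc, w):
        assert weight_from_accuracy(acc) == pytest.approx(w, abs=1e-4)

    def test_clipping_keeps_weight_finite(self):
        w = weight_from_accuracy(1.0, epsilon=1e-6)
        assert w == pytest.approx(np.log((1 - 1e-6) / 1e-6), rel=1e-9)
        assert np.isfinite(weight_from_accuracy(0.0))


class TestVoting:
    def test_m2_single_model_thresholds_at_own_cutoff(self):
        labels = np.array([1, 1, 0, 0])
        out = mk_output([0.9, 0.7, 0.3, 0.1])
        votes, cutoffs = make_votes([out], "M2", labels)
        tau = cutoffs["per_model"][0]
        assert (votes[0] == (out.prob >= tau)).all()

    def test_identical_models_make_m1_equal_m2(self):
        labels = np.array([1, 1, 0, 0, 1, 0])
        out = mk_output([0.9, 0.7, 0.35, 0.1, 0.6, 0.45])
        v1, _ = make_votes([out, out], "M1", labels)
        v2, _ = make_votes([out, out], "M2", labels)
        assert (v1 == v2).all()

    def test_m1_uses_mean_cutoff_worked_example(self):
        """Cutoffs 0.4 and 0.6: a probe probability of 0.5 votes (1,1) under
        the mean cutoff 0.5 but (1,0) under per-model cutoffs."""
        labels = np.array([1, 0, 1, 0, 1])
        a = mk_output([0.9, 0.3, 0.5, 0.35, 0.45])   # own cutoff 0.4
        b = mk_output([0.9, 0.5, 0.7, 0.55, 0.65])   # own cutoff 0.6
        v1, c1 = make_votes([a, b], "M1", labels)
        v2, c2 = make_votes([a, b], "M2", labels)
        assert c1["per_model"] == pytest.approx([0.4, 0.6], abs=0.051)
        assert c1["mean"] == pytest.approx(0.5, abs=0.051)
        probe = 2   # lesion with probabilities (0.5, 0.7)->a:0.5, b:0.7
        assert v1[0, probe] == 1 and v2[0, probe] == 1
        probe_b = np.where(np.isclose(b.prob, 0.5))[0][0]
        assert v1[1, probe_b] == 1    # 0.5 >= mean cutoff 0.5
        assert v2[1, probe_b] == 0    # 0.5 < own cutoff ~0.6

    def test_m3_votes_are_crisp_labels(self):
        labels = np.array([1, 0, 1, 0])
        out = mk_output([0.9, 0.2, 0.8, 0.4], crisp=[1, 0, 1, 1])
        votes, cutoffs = make_votes([out], "M3", labels)
        assert (votes[0] == [1, 0, 1, 1]).all()
        assert "crisp_mean_cutoff" in cutoffs

    def test_unanimous_votes_win_regardless_of_weights(self):
        votes = np.ones((3, 5), dtype=int)
        pred = aggregate_votes(votes, "weighted", accuracies=[0.51, 0.7, 0.99])
        assert (pred.label == 1).all()

    def test_equal_accuracies_reduce_to_simple_majority(self):
        rng = np.random.default_rng(6)
        votes = rng.integers(0, 2, (5, 40))
        simple = aggregate_votes(votes, "simple")
        weighted = aggregate_votes(votes, "weighted", accuracies=[0.7] * 5)
        assert (simple.label == weighted.label).all()
        assert simple.score == pytest.approx(weighted.score)

    def test_strong_model_overturns_simple_majority(self):
        """Votes (1,1,0) with accuracies (.55,.55,.95): the weighted score is
        2*ln(.55/.45) / (2*ln(.55/.45)+ln(19)) ~ 0.120, so the label flips."""
        votes = np.array([[1], [1], [0]])
        pred = aggregate_votes(votes, "weighted", accuracies=[0.55, 0.55, 0.95])
        assert pred.score[0] == pytest.approx(0.120, abs=5e-4)
        assert pred.label[0] == 0
        assert aggregate_votes(votes, "simple").label[0] == 1

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(7)
        votes = rng.integers(0, 2, (4, 30))
        accs = [0.6, 0.7, 0.8, 0.9]
        base = aggregate_votes(votes, "weighted", accuracies=accs)
        # scaling all weights by a positive constant == changing log base
        w = base.weights * 7.3
        score = w @ votes / w.sum()
        assert ((score >= 0.5).astype(int) == base.label).all()

    def test_tie_at_half_calls_positive(self):
        votes = np.array([[1], [0]])
        assert aggregate_votes(votes, "simple").label[0] == 1

    def test_all_models_at_chance_rejected_for_weighting(self):
        votes = np.array([[1, 0], [0, 1]])
        with pytest.raises(ValueError, match="simple voting"):
            aggregate_votes(votes, "weighted", accuracies=[0.5, 0.4])

    def test_degenerate_identical_crisp_votes(self):
        labels = np.array([1, 1, 0, 1])
        out = mk_output([0.9, 0.8, 0.7, 0.6], crisp=[1, 1, 1, 1])
        votes, _ = make_votes([out], "M3", labels)
        pred = aggregate_votes(votes, "simple")
        assert (pred.label == 1).all()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            EnsembleConfig(strategy="M4")
        with pytest.raises(ValueError):
            EnsembleConfig(voting="quadratic")
        with pytest.raises(ValueError):
            EnsembleConfig(top_k=0)


@pytest.fixture(scope="module")
def outputs():
    rng = np.random.default_rng(9)
    n = 80
    labels = rng.integers(0, 2, n)
    outs = []
    for i in range(6):
        noise = rng.normal(0, 0.35 + 0.05 * i, n)
        prob = np.clip(0.5 + 0.4 * (labels - 0.5) + noise, 0, 1)
        crisp = (prob >= 0.5).astype(float)
        outs.append(ModelOutput(feature=f"f{i}", algorithm="x",
                                lesion_ids=np.arange(n), prob=prob,
                                crisp=crisp,
                                accuracy=float((crisp == labels).mean())))
    return outs, labels


class TestTopkSweep:
    def test_report_shape_and_k1_equals_single_model(self, outputs):
        outs, labels = outputs
        report = run_topk_sweep(outs, labels, k_max=6)
        assert len(report) == 6 * 3   # k x strategies
        assert sorted(report.k.unique()) == list(range(1, 7))
        row = report[(report.k == 1) & (report.strategy == "M3")].iloc[0]
        single_acc = 100 * (outs[0].crisp == labels).mean()
        assert row.accuracy == pytest.approx(single_acc)

    def test_k_beyond_available_models_rejected(self, outputs):
        outs, labels = outputs
        with pytest.raises(ValueError, match="exceeds"):
            run_topk_sweep(outs, labels, k_max=7)

    def test_nan_outputs_rejected(self, outputs):
        outs, labels = outputs
        import dataclasses
        bad = dataclasses.replace(outs[0])
        bad.prob = bad.prob.copy()
        bad.prob[0] = np.nan
        with pytest.raises(ValueError, match="unscored"):
            make_votes([bad], "M1", labels)
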