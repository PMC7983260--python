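import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from vemgae import (
    TrainConfig,
    aupr,
    auroc,
    binary_metrics,
    compute_report,
    confusion_counts,
    cross_validate,
    make_folds,
    masked_training_matrix,
    metrics_at_specificity,
    topk_true_positives,
)


def brute_force_auroc(scores, labels):
    """Oracle: count positive-negative pairs (ties worth 1/2)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_aupr(scores, labels):
    """Oracle: cumulative-precision enumeration over tied-score blocks."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    n_pos = y.sum()
    area = prev_recall = 0.0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp = y[: j].sum()
        precision = tp / j
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return area


def random_instance(rng, n):
    labels = np.zeros(n)
    labels[: max(1, n // 10)] = 1
    rng.shuffle(labels)
    scores = np.round(rng.random(n), 2)  # rounding forces ties
    return scores, labels


class TestFolds:
    def test_ten_positives_five_equal_folds(self, toy_assoc):
        values = np.zeros((5, 4))
        values.ravel()[:10] = 1
        Y = toy_assoc.__class__(values, [f"r{i}" for i in range(5)], [f"c{j}" for j in range(4)])
        plan = make_folds(Y, 5, seed=0)
        sizes = [len(plan.fold_positives(f)) for f in range(1, 6)]
        assert sizes == [2] * 5

    def test_folds_partition_positives(self, small_dataset):
        Y = small_dataset[0]
        plan = make_folds(Y, 5, seed=1)
        all_pos = {tuple(ij) for ij in Y.positives}
        seen = [ij for f in range(1, 6) for ij in plan.fold_positives(f)]
        assert set(seen) == all_pos and len(seen) == len(all_pos)

    def test_same_seed_same_plan(self, small_dataset):
        Y = small_dataset[0]
        assert make_folds(Y, 5, 7).fold_assignments == make_folds(Y, 5, 7).fold_assignments

    def test_too_few_positives_rejected(self, toy_assoc):
        with pytest.raises(ValueError):
            make_folds(toy_assoc, 5, 0)


class TestMasking:
    def test_mask_then_restore(self, small_dataset):
        Y = small_dataset[0]
        plan = make_folds(Y, 5, 0)
        masked = masked_training_matrix(Y, plan, 2)
        restored = masked.values.copy()
        for (i, j) in plan.fold_positives(2):
            assert masked.values[i, j] == 0.0
            restored[i, j] = 1.0
        assert np.array_equal(restored, Y.values)

    def test_masked_positive_count(self, small_dataset):
        Y = small_dataset[0]
        plan = make_folds(Y, 5, 0)
        masked = masked_training_matrix(Y, plan, 1)
        held = len(plan.fold_positives(1))
        assert masked.values.sum() == Y.values.sum() - held


class TestConfusionAndMetrics:
    def test_basic_counts(self):
        assert confusion_counts([0.9, 0.1], [1, 0], 0.5) == (1, 0, 1, 0)

    def test_threshold_zero_all_positive(self):
        tp, fp, tn, fn = confusion_counts([0.2, 0.7], [0, 1], 0.0)
        assert (tp + fp, tn + fn) == (2, 0)

    def test_threshold_above_max_all_negative(self):
        tp, fp, tn, fn = confusion_counts([0.2, 0.7], [0, 1], 0.71)
        assert (tn + fn, tp + fp) == (2, 0)

    def test_perfect_prediction(self):
        m = binary_metrics(1, 0, 1, 0)
        assert all(m[k] == 1.0 for k in ("sensitivity", "specificity", "accuracy", "precision", "f1", "mcc"))

    def test_perfectly_wrong_mcc(self):
        assert binary_metrics(0, 1, 0, 1)["mcc"] == -1.0

    def test_hand_computed_table(self):
        m = binary_metrics(2, 1, 3, 2)
        assert m["sensitivity"] == 0.5
        assert m["specificity"] == 0.75
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["accuracy"] == pytest.approx(5 / 8)
        assert m["f1"] == pytest.approx(4 / 7)
        assert m["mcc"] == pytest.approx((2 * 3 - 1 * 2) / np.sqrt(4 * 3 * 5 * 4))

    def test_zero_denominators_define_zero(self):
        m = binary_metrics(0, 0, 5, 5)
        assert m["precision"] == 0.0 and m["f1"] == 0.0 and m["mcc"] == 0.0

    def test_mcc_symmetric_under_class_swap(self):
        # swapping classes and predictions maps (tp, fp, tn, fn) -> (tn, fn, tp, fp)
        assert binary_metrics(7, 2, 11, 3)["mcc"] == pytest.approx(binary_metrics(11, 3, 7, 2)["mcc"])


class TestAuroc:
    def test_worked_example(self):
        assert auroc([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0]) == 0.75

    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_permutation_null_near_half(self):
        rng = np.random.default_rng(0)
        n = 4000
        labels = (rng.random(n) < 0.3).astype(int)
        scores = rng.random(n)
        se = np.sqrt((n * 0.3 * 0.7 + 1) / (12 * (n * 0.3) * (n * 0.7)))
        assert abs(auroc(scores, labels) - 0.5) < 3 * se

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        scores, labels = random_instance(rng, 200)
        assert auroc(np.exp(3 * scores), labels) == pytest.approx(auroc(scores, labels), abs=1e-12)

    def test_matches_oracles_with_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            scores, labels = random_instance(rng, int(rng.integers(20, 120)))
            ours = auroc(scores, labels)
            assert ours == pytest.approx(brute_force_auroc(scores, labels), abs=1e-12)
            assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestAupr:
    def test_perfect_ranking(self):
        assert aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        assert aupr([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0]) == pytest.approx(0.5 + (2 / 3) * 0.5)

    def test_uniform_scores_give_prevalence(self):
        labels = np.array([1, 0, 0, 1, 0, 0, 0, 0])
        assert aupr(np.full(8, 0.3), labels) == pytest.approx(0.25)

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError):
            aupr([0.1], [0])

    def test_matches_oracles(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            scores, labels = random_instance(rng, int(rng.integers(20, 120)))
            ours = aupr(scores, labels)
            assert ours == pytest.approx(brute_force_aupr(scores, labels), abs=1e-12)
            assert ours == pytest.approx(average_precision_score(labels, scores), abs=1e-12)


class TestFixedSpecificity:
    def test_threshold_excludes_top_five_percent_of_negatives(self):
        neg = np.linspace(0.1, 0.9, 100)
        pos = np.array([0.95, 0.97])
        scores = np.concatenate([neg, pos])
        labels = np.concatenate([np.zeros(100), np.ones(2)])
        m = metrics_at_specificity(scores, labels, 0.95)
        assert m["specificity"] == 0.95  # exactly 5 negatives remain above
        assert m["sensitivity"] == 1.0

    def test_high_specificity_with_distinct_scores(self):
        rng = np.random.default_rng(4)
        scores = rng.permutation(np.linspace(0, 1, 50))
        labels = (scores > 0.8).astype(int)
        m = metrics_at_specificity(scores, labels, 0.999)
        assert m["specificity"] == 1.0

    def test_perfect_separation_keeps_full_sensitivity(self):
        scores = np.array([0.9, 0.95, 0.2, 0.1, 0.3])
        labels = np.array([1, 1, 0, 0, 0])
        for sp in (0.5, 0.95, 0.99):
            assert metrics_at_specificity(scores, labels, sp)["sensitivity"] == 1.0

    def test_all_negatives_tied_at_max_rejected(self):
        with pytest.raises(ValueError, match="unreachable"):
            metrics_at_specificity([0.9, 0.9, 0.5], [0, 0, 1], 0.95)


class TestTopK:
    def test_perfectly_ranked_positives(self):
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0])
        counts = topk_true_positives(scores, labels, ks=(2, 4))
        assert counts == {2: 2, 4: 3}

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            topk_true_positives([0.5], [1], ks=(2,))

    def test_random_scores_expected_count(self):
        rng = np.random.default_rng(5)
        prevalence, k, n = 0.2, 50, 500
        counts = []
        for _ in range(40):
            labels = (rng.random(n) < prevalence).astype(int)
            counts.append(topk_true_positives(rng.random(n), labels, ks=(k,))[k])
        assert np.mean(counts) == pytest.approx(k * prevalence, abs=2.0)


class TestCrossValidate:
    def test_small_run_counts_and_reproducibility(self, small_dataset, tiny_config):
        Y, X_l, X_d, _ = small_dataset
        res = cross_validate(Y, X_l, X_d, tiny_config, k_folds=5, seed=2)
        n_zero = int((Y.values == 0).sum())
        held_total = 0
        for fold, report in enumerate(res.fold_reports, 1):
            held = len(res.plan.fold_positives(fold))
            held_total += held
            assert 0.0 <= report.auroc <= 1.0 and 0.0 <= report.aupr <= 1.0
        assert held_total == int(Y.values.sum())
        assert len(res.pooled_scores) == held_total + 5 * n_zero

        res2 = cross_validate(Y, X_l, X_d, tiny_config, k_folds=5, seed=2)
        assert np.array_equal(res.pooled_scores, res2.pooled_scores)
        assert res.pooled.auroc == res2.pooled.auroc

    def test_report_serialisable(self, small_dataset, tiny_config):
        Y, X_l, X_d, _ = small_dataset
        res = cross_validate(Y, X_l, X_d, tiny_config, k_folds=3, seed=0)
        d = res.pooled.to_dict()
        assert set(d) == {"auroc", "aupr", "at_specificity", "topk_counts"}
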