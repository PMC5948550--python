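"""Evaluation harness tests, cross-checked against sklearn contingency oracles."""

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, confusion_matrix as sk_confusion

from fallkit.evaluate import (
    ConfusionMatrix,
    balanced_accuracy_at,
    candidate_thresholds,
    confusion_at,
    cross_validate,
    kappa_report,
    metrics,
    stratified_folds,
    train_threshold,
)

# the published 10-fold mean confusion matrix (451 files per fold):
# rows = prediction, columns = ground truth
TABLE5 = ConfusionMatrix(TP=178.7, FN=1.3, TN=269.8, FP=1.2)


class TestStratifiedFolds:
    def test_fold_sizes_and_proportions(self, rng):
        labels = np.concatenate([np.ones(18, bool), np.zeros(42, bool)])
        rng.shuffle(labels)
        assignment = stratified_folds(labels, k=10, seed=7)
        sizes = np.bincount(assignment, minlength=10)
        assert sizes.max() - sizes.min() <= 1
        for fold in range(10):
            n_fall = labels[assignment == fold].sum()
            assert abs(n_fall - 1.8) <= 1

    def test_even_split_exact(self):
        labels = np.array([True] * 10 + [False] * 10)
        assignment = stratified_folds(labels, k=2, seed=0)
        for fold in (0, 1):
            mask = assignment == fold
            assert mask.sum() == 10
            assert labels[mask].sum() == 5

    def test_deterministic_given_seed(self):
        labels = np.array([True] * 9 + [False] * 21)
        a = stratified_folds(labels, k=3, seed=5)
        b = stratified_folds(labels, k=3, seed=5)
        assert np.array_equal(a, b)

    def test_sparse_class_rejected(self):
        labels = np.array([True] * 2 + [False] * 20)
        with pytest.raises(ValueError):
            stratified_folds(labels, k=5, seed=0)


class TestTrainThreshold:
    def test_separated_classes_midpoint(self):
        scores = np.array([10.0, 12.0, 1.0, 2.0])
        labels = np.array([True, True, False, False])
        t = train_threshold(scores, labels)
        assert t == 6.0
        assert balanced_accuracy_at(scores, labels, t) == 1.0

    def test_tie_returns_smallest_maximizer(self):
        scores = np.array([10.0, 12.0, 1.0, 2.0, 11.0])
        labels = np.array([True, True, False, False, False])
        # brute force over every candidate: 6.0 is the smallest maximizer
        cands = candidate_thresholds(scores)
        accs = [balanced_accuracy_at(scores, labels, t) for t in cands]
        best = max(accs)
        smallest = min(t for t, a in zip(cands, accs) if np.isclose(a, best))
        assert train_threshold(scores, labels) == smallest == 6.0

    def test_interleaved_scores_coin_flip_lowest_sentinel(self):
        scores = np.array([1.0, 2.0, 3.0, 4.0])
        labels = np.array([True, False, True, False])
        t = train_threshold(scores, labels)
        assert balanced_accuracy_at(scores, labels, t) == 0.5
        assert t == 0.0  # below-min sentinel

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            train_threshold(np.array([1.0, 2.0]), np.array([True, True]))

    def test_optimal_by_construction_random_instances(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 50))
            scores = np.round(rng.normal(size=n) * 10, 1)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            t = train_threshold(scores, labels)
            acc_t = balanced_accuracy_at(scores, labels, t)
            grid = np.concatenate([candidate_thresholds(scores), scores])
            assert all(acc_t >= balanced_accuracy_at(scores, labels, g) - 1e-12 for g in grid)


class TestMetrics:
    def test_published_mean_matrix_sensitivity(self):
        m = metrics(TABLE5)
        assert round(100 * m["SEN"], 2) == 99.28

    def test_perfect_detector(self):
        m = metrics(ConfusionMatrix(TP=5, FN=0, TN=7, FP=0))
        assert m == {"SEN": 1.0, "SPE": 1.0, "ACC": 1.0}

    def test_small_arithmetic(self):
        m = metrics(ConfusionMatrix(TP=1, FN=1, TN=3, FP=1))
        assert m["SEN"] == 0.5
        assert m["SPE"] == 0.75
        assert m["ACC"] == 0.625

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(TP=0, FN=0, TN=3, FP=1))

    def test_agreement_with_sklearn_on_random_tables(self, rng):
        for _ in range(1000):
            y_true = rng.random(30) < rng.uniform(0.2, 0.8)
            y_pred = rng.random(30) < rng.uniform(0.2, 0.8)
            if len(set(y_true)) < 2:
                continue
            tn, fp, fn, tp = sk_confusion(y_true, y_pred, labels=[False, True]).ravel()
            cm = ConfusionMatrix(TP=tp, FN=fn, TN=tn, FP=fp)
            m = metrics(cm)
            assert m["SEN"] == pytest.approx(tp / (tp + fn))
            assert m["SPE"] == pytest.approx(tn / (tn + fp))
            rep = kappa_report(cm)
            assert rep["kappa"] == pytest.approx(
                cohen_kappa_score(y_true, y_pred), abs=1e-12
            )


class TestKappa:
    def test_published_matrix_observed_accuracy(self):
        rep = kappa_report(TABLE5)
        assert round(rep["observed_accuracy"], 4) == 0.9945

    def test_published_matrix_standard_expected_accuracy(self):
        # marginal products: (271.1*271.0 + 179.9*180.0) / 451^2
        rep = kappa_report(TABLE5)
        assert rep["expected_accuracy"] == pytest.approx(0.5204, abs=5e-5)

    def test_variant_kappa_with_supplied_expected_accuracy(self):
        rep = kappa_report(TABLE5, expected_accuracy=0.3990)
        assert rep["kappa_variant"] == pytest.approx(0.9908, abs=5e-4)

    def test_perfect_diagonal_kappa_one(self):
        rep = kappa_report(ConfusionMatrix(TP=10, FN=0, TN=20, FP=0))
        assert rep["kappa"] == pytest.approx(1.0)

    def test_degenerate_expected_accuracy_rejected(self):
        with pytest.raises(ValueError):
            kappa_report(ConfusionMatrix(TP=0, FN=0, TN=10, FP=0))


class TestCrossValidate:
    def test_separable_corpus_perfect_every_fold(self, default_scored):
        res = cross_validate(
            default_scored["score"].to_numpy(),
            default_scored["is_fall"].to_numpy(),
            k=10,
            seed=1,
        )
        assert np.all(res.fold_acc == 1.0)
        rel_spread = res.fold_thresholds.std(ddof=1) / res.fold_thresholds.mean()
        assert rel_spread < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(np.arange(20.0), np.ones(20, bool), k=2, seed=0)

    def test_invariant_to_file_order(self, rng):
        scores = np.concatenate([rng.uniform(50, 100, 12), rng.uniform(0, 40, 28)])
        labels = np.array([True] * 12 + [False] * 28)
        res_a = cross_validate(scores, labels, k=4, seed=3)
        perm = rng.permutation(40)
        res_b = cross_validate(scores[perm], labels[perm], k=4, seed=3)
        assert np.allclose(sorted(res_a.fold_acc), sorted(res_b.fold_acc))
        assert res_a.pooled_cm.TP == res_b.pooled_cm.TP

    def test_veto_improves_specificity_on_hard_corpus(self, hard_scored):
        res_on = cross_validate(
            hard_scored["on"]["score"].to_numpy(),
            hard_scored["on"]["is_fall"].to_numpy(),
            k=5,
            seed=2,
        )
        res_off = cross_validate(
            hard_scored["off"]["score"].to_numpy(),
            hard_scored["off"]["is_fall"].to_numpy(),
            k=5,
            seed=2,
        )
        assert res_on.fold_spe.mean() >= res_off.fold_spe.mean()

    def test_mean_matrix_averages_fold_counts(self, rng):
        scores = np.concatenate([rng.uniform(50, 100, 10), rng.uniform(0, 40, 20)])
        labels = np.array([True] * 10 + [False] * 20)
        res = cross_validate(scores, labels, k=5, seed=9)
        assert res.mean_cm.total == pytest.approx(30 / 5)
        assert res.pooled_cm.total == 30
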