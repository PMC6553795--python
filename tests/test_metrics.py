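import numpy as np
import pandas as pd
import pytest
from scipy.stats import mannwhitneyu
from sklearn.metrics import average_precision_score, roc_auc_score

from helpers_oracles import average_precision_reference

from giddi import (
    aupr,
    auroc,
    average_curves,
    f1_score_at,
    max_f1_threshold,
    permutation_test_mean,
    pr_points,
    precision_at_k,
    rank_predictions,
    roc_points,
)
from giddi.metrics import GRID_SIZE


def random_instance(rng, n=40):
    labels = np.zeros(n, dtype=int)
    labels[: rng.integers(1, n)] = 1
    rng.shuffle(labels)
    scores = np.round(rng.random(n), 2)  # rounding forces plenty of ties
    return scores, labels


class TestAuroc:
    def test_perfect_and_inverted_ranking(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0
        assert auroc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_all_tied_scores_give_half(self):
        assert auroc([0.5] * 6, [1, 0, 1, 0, 0, 1]) == pytest.approx(0.5)

    def test_agrees_with_mann_whitney_statistic(self):
        rng = np.random.default_rng(10)
        for _ in range(200):
            scores, labels = random_instance(rng)
            n1, n0 = labels.sum(), len(labels) - labels.sum()
            if n1 == 0 or n0 == 0:
                continue
            u = mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
            assert auroc(scores, labels) == pytest.approx(u / (n1 * n0), abs=1e-12)
            assert auroc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])


class TestAupr:
    def test_perfect_ranking_scores_one(self):
        assert aupr([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_agrees_with_step_oracle_and_sklearn(self):
        rng = np.random.default_rng(20)
        for _ in range(200):
            scores, labels = random_instance(rng)
            if labels.sum() == 0:
                continue
            ref = average_precision_reference(list(scores), list(labels))
            assert aupr(scores, labels) == pytest.approx(ref, abs=1e-12)
            assert aupr(scores, labels) == pytest.approx(
                average_precision_score(labels, scores), abs=1e-12
            )

    def test_no_positive_rejected(self):
        with pytest.raises(ValueError):
            aupr([0.3, 0.2], [0, 0])


class TestRankedPredictions:
    def test_sorted_with_lexicographic_tiebreak(self):
        ranked = rank_predictions(
            [("C", "D"), ("A", "B"), ("A", "C")], [0.5, 0.5, 0.9], [0, 1, 1]
        )
        assert list(zip(ranked["drug_a"], ranked["drug_b"])) == [
            ("A", "C"),
            ("A", "B"),
            ("C", "D"),
        ]

    def test_precision_at_k(self):
        ranked = rank_predictions(
            [("A", "B"), ("A", "C"), ("B", "C"), ("B", "D")],
            [0.9, 0.8, 0.3, 0.1],
            [1, 0, 1, 0],
        )
        assert precision_at_k(ranked, 1) == 1.0
        assert precision_at_k(ranked, 2) == 0.5
        assert precision_at_k(ranked, 4) == 0.5
        with pytest.raises(ValueError):
            precision_at_k(ranked, 5)


class TestCurves:
    def test_roc_points_small_example(self):
        fpr, tpr = roc_points([0.9, 0.7, 0.4, 0.2], [1, 0, 1, 0])
        assert fpr.tolist() == [0.0, 0.0, 0.5, 0.5, 1.0]
        assert tpr.tolist() == [0.0, 0.5, 0.5, 1.0, 1.0]

    def test_pr_points_small_example(self):
        recall, precision = pr_points([0.9, 0.7, 0.4, 0.2], [1, 0, 1, 0])
        assert recall.tolist() == [0.0, 0.5, 0.5, 1.0, 1.0]
        assert precision.tolist() == [1.0, 1.0, 0.5, 2 / 3, 0.5]

    def test_averaging_identical_runs_is_identity_on_grid(self):
        scores = np.array([0.9, 0.7, 0.4, 0.2])
        labels = np.array([1, 0, 1, 0])
        run = roc_points(scores, labels)
        avg = average_curves([run, run, run], "ROC")
        assert avg.n_runs == 3
        assert len(avg.grid) == GRID_SIZE
        assert np.allclose(avg.mean_y, np.interp(avg.grid, *run))

    def test_mean_of_two_constant_pr_runs(self):
        # two flat precision curves at 1.0 and 0.5 average to 0.75
        r1 = (np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        r2 = (np.array([0.0, 1.0]), np.array([0.5, 0.5]))
        avg = average_curves([r1, r2], "PR")
        assert np.allclose(avg.mean_y, 0.75)

    def test_averaged_curve_area_tracks_auroc(self):
        rng = np.random.default_rng(4)
        scores, labels = random_instance(rng, n=200)
        avg = average_curves([roc_points(scores, labels)], "ROC")
        area = float(np.trapezoid(avg.mean_y, avg.grid))
        assert area == pytest.approx(auroc(scores, labels), abs=5e-3)


class TestPermutationTest:
    def test_exhaustive_small_case_exact_value(self):
        # groups {0,0,0} vs {1,1,1}: 20 assignments, 2 reach |diff| = 1
        assert permutation_test_mean([0, 0, 0], [1, 1, 1], n_perm=1000) == pytest.approx(
            0.1
        )

    def test_identical_groups_give_p_one(self):
        assert permutation_test_mean([1.0, 2.0], [2.0, 1.0], n_perm=1000) == 1.0

    def test_monte_carlo_branch_never_returns_zero(self):
        rng = np.random.default_rng(5)
        a = rng.normal(5.0, 0.1, size=30)
        b = rng.normal(0.0, 0.1, size=30)
        p = permutation_test_mean(a, b, n_perm=999, seed=1)
        assert p == pytest.approx(1 / 1000)

    def test_monte_carlo_close_to_exact_on_moderate_case(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.4, 1.0, size=8)
        b = rng.normal(0.0, 1.0, size=8)
        exact = permutation_test_mean(a, b, n_perm=20_000)  # C(16,8)=12870 -> exhaustive
        mc = permutation_test_mean(a, b, n_perm=10_000, seed=2)
        assert abs(mc - exact) < 0.02


class TestF1Cutoff:
    def test_f1_arithmetic(self):
        scores = np.array([0.9, 0.6, 0.4, 0.1])
        labels = np.array([1, 0, 1, 0])
        assert f1_score_at(scores, labels, 0.5) == pytest.approx(0.5)  # tp=1 fp=1 fn=1
        assert f1_score_at(scores, labels, 0.3) == pytest.approx(0.8)
        assert f1_score_at(scores, labels, 0.95) == 0.0

    def test_grid_maximum_with_tie_toward_larger_cutoff(self):
        # any cutoff in (0.4, 0.9] achieves F1 = 1; ties resolve to 0.9
        runs = [([0.9, 0.4], [1, 0])]
        assert max_f1_threshold(runs) == pytest.approx(0.9)

    def test_averages_over_runs(self):
        # run 1 prefers low cutoffs, run 2 high; the mean picks the best joint
        runs = [([0.8, 0.3], [1, 1]), ([0.9, 0.35], [1, 0])]
        cut = max_f1_threshold(runs)
        assert 0.35 < cut <= 0.8

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            max_f1_threshold([([0.5, 0.4], [0, 0])])
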