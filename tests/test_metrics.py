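"""Metric implementations against independent brute-force oracles."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score, roc_auc_score

from gdafusion.metrics import (
    MetricReport,
    accuracy,
    aupr,
    confusion_counts,
    evaluate_by_category,
    f_max,
    mean_report,
    roc_auc,
)


from oracles import (
    aupr_oracle,
    auc_oracle,
    fmax_oracle,
    random_metric_instances as random_instances,
)

class TestConfusionCounts:
    @pytest.mark.parametrize("labels,scores,t,expected", [
        ([1, 0], [0.9, 0.1], 0.5, (1, 0, 1, 0)),
        ([1, 1, 0, 0], [0.9, 0.2, 0.8, 0.1], 0.5, (1, 1, 1, 1)),
    ])
    def test_worked_examples(self, labels, scores, t, expected):
        assert confusion_counts(labels, scores, t) == expected

    def test_threshold_zero_predicts_everything_positive(self):
        tp, fp, tn, fn = confusion_counts([1, 0, 1], [0.2, 0.0, 0.9], 0.0)
        assert (tn, fn) == (0, 0)
        assert (tp, fp) == (2, 1)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="empty"):
            confusion_counts([], [], 0.5)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_worked_example_three_quarters(self):
        # 3 of 4 (pos, neg) pairs concordant
        assert roc_auc([1, 0, 1, 0], [0.9, 0.6, 0.4, 0.1]) == 0.75

    def test_all_tied_scores_give_half(self):
        assert roc_auc([1, 0, 1, 0], [0.5] * 4) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 1], [0.2, 0.4])

    def test_complement_identity_for_tie_free_scores(self, rng):
        labels = [1, 0, 1, 0, 0, 1, 0]
        scores = rng.permutation(len(labels)) / 10.0
        assert abs(roc_auc(labels, scores)
                   + roc_auc(labels, [-s for s in scores]) - 1.0) < 1e-12

    def test_invariant_under_monotone_transform(self, rng):
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        scores = rng.random(20)
        a = roc_auc(labels, scores)
        b = roc_auc(labels, np.exp(3 * scores))
        assert abs(a - b) < 1e-12


class TestAupr:
    def test_perfect_ranking_is_one(self):
        assert aupr([0, 1, 1], [0.1, 0.8, 0.9]) == 1.0

    def test_worst_ranking_two_samples(self):
        assert aupr([1, 0], [0.1, 0.9]) == 0.5

    def test_random_scores_approach_prevalence(self):
        rng = np.random.default_rng(1)
        n, pi = 4000, 0.25
        labels = (rng.random(n) < pi).astype(int)
        scores = rng.random(n)
        assert abs(aupr(labels, scores) - labels.mean()) < 0.03

    def test_no_positive_errors(self):
        with pytest.raises(ValueError, match="positive"):
            aupr([0, 0], [0.4, 0.2])


class TestFmax:
    def test_worked_example(self):
        # thresholds: <=0.2 all positive -> F=0.8; 0.8 -> F=0.5; 0.9 -> 2/3
        value, threshold = f_max([1, 0, 1], [0.9, 0.8, 0.2])
        assert abs(value - 0.8) < 1e-12
        assert threshold == 0.2  # smallest maximizing threshold

    def test_perfect_separation(self):
        value, _ = f_max([0, 1], [0.1, 0.9])
        assert value == 1.0

    def test_dominates_f_at_half(self, rng):
        for labels, scores in random_instances(30, seed=3):
            tp, fp, _, fn = confusion_counts(labels, scores, 0.5)
            f_half = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
            assert f_max(labels, scores)[0] >= f_half - 1e-12


class TestOracleEquivalence:
    def test_fuzz_against_brute_force(self):
        for labels, scores in random_instances(200, seed=7):
            assert abs(roc_auc(labels, scores) - auc_oracle(labels, scores)) < 1e-9
            assert abs(aupr(labels, scores) - aupr_oracle(labels, scores)) < 1e-9
            assert abs(f_max(labels, scores)[0] - fmax_oracle(labels, scores)) < 1e-9

    def test_cross_check_against_sklearn_tie_free(self):
        for labels, scores in random_instances(50, seed=11, with_ties=False):
            assert abs(roc_auc(labels, scores)
                       - roc_auc_score(labels, scores)) < 1e-9
            assert abs(aupr(labels, scores)
                       - average_precision_score(labels, scores)) < 1e-9


class TestReports:
    def test_mean_report_is_arithmetic_mean(self):
        r1 = MetricReport(0.8, 0.7, 0.6, 0.5, 0.4, n_test=10)
        r2 = MetricReport(0.6, 0.9, 0.8, 0.7, 0.2, n_test=10)
        m = mean_report([r1, r2])
        assert m.auc == pytest.approx(0.7)
        assert m.aupr == pytest.approx(0.8)
        assert m.f_max == pytest.approx(0.7)
        assert m.accuracy == pytest.approx(0.6)

    def test_accuracy_threshold_is_half(self):
        assert accuracy([1, 0, 1, 0], [0.6, 0.4, 0.4, 0.6]) == 0.5
        assert accuracy([1, 0], [0.5, 0.49]) == 1.0  # boundary inclusive


class TestEvaluateByCategory:
    def test_identical_multisets_equal_auc(self):
        labels = [1, 0, 1, 0, 1, 0, 1, 0]
        scores = [0.9, 0.3, 0.6, 0.5, 0.9, 0.3, 0.6, 0.5]
        dids = ["a1", "a2", "a1", "a2", "b1", "b2", "b1", "b2"]
        cats = {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        out = evaluate_by_category(labels, scores, dids, cats)
        assert out["categories"]["A"]["auc"] == out["categories"]["B"]["auc"]

    def test_single_class_category_undefined_and_excluded(self):
        labels = [1, 1, 1, 0]
        scores = [0.9, 0.8, 0.7, 0.1]
        dids = ["a1", "a1", "b1", "b1"]
        cats = {"a1": "A", "b1": "B"}
        out = evaluate_by_category(labels, scores, dids, cats)
        assert out["categories"]["A"]["auc"] is None
        assert out["correlations"]["auc_vs_log_pair_count"] is None

    def test_unmapped_disease_errors(self):
        with pytest.raises(KeyError, match="d9"):
            evaluate_by_category([1, 0], [0.9, 0.1], ["d9", "d9"], {})

    def test_pearson_matches_covariance_oracle(self):
        # 3 categories with hand-built AUCs and sizes
        labels, scores, dids = [], [], []
        # per-category (n pairs, label list, score list): distinct AUCs
        spec = {
            "A": ([1, 0, 1, 0], [0.9, 0.1, 0.8, 0.2]),            # AUC 1.0
            "B": ([1, 0, 1, 0, 1, 0], [0.9, 0.5, 0.4, 0.1, 0.7, 0.6]),
            "C": ([1, 0, 0, 1, 0, 1, 0, 0], [0.2, 0.9, 0.1, 0.5, 0.4,
                                             0.3, 0.6, 0.05]),
        }
        cats = {}
        for cat, (ys, ss) in spec.items():
            for i, (y, s) in enumerate(zip(ys, ss)):
                did = f"{cat.lower()}{i}"
                cats[did] = cat
                labels.append(y)
                scores.append(s)
                dids.append(did)
        out = evaluate_by_category(labels, scores, dids, cats)
        defined = [c for c, e in out["categories"].items() if e["auc"] is not None]
        aucs = np.array([out["categories"][c]["auc"] for c in defined])
        x = np.log10([out["categories"][c]["n_pairs"] for c in defined])
        expected = (
            np.mean((aucs - aucs.mean()) * (x - x.mean()))
            / (aucs.std() * x.std())
        )
        assert out["correlations"]["auc_vs_log_pair_count"] == pytest.approx(expected)
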