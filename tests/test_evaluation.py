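"""Metrics against hand computations and brute-force oracles."""

import numpy as np
import pytest
from itertools import combinations

from ocufusion.evaluation import (
    aggregate_folds,
    comparison_table,
    confusion_matrix,
    evaluate_predictions,
    macro_auc_ovo,
    macro_metrics,
    normalize_confusion,
    paired_ttest,
)


def brute_force_auc(scores_pos, scores_neg):
    """Exhaustive Mann-Whitney pair enumeration; ties count 1/2."""
    wins = sum(
        1.0 if p > n else 0.5 if p == n else 0.0
        for p in scores_pos
        for n in scores_neg
    )
    return wins / (len(scores_pos) * len(scores_neg))


def brute_force_ovo(y, probs):
    c = probs.shape[1]
    pair_vals = []
    for i, j in combinations(range(c), 2):
        sel = (y == i) | (y == j)
        yi, pi, pj = y[sel], probs[sel, i], probs[sel, j]
        if not ((yi == i).any() and (yi == j).any()):
            continue
        a_ij = brute_force_auc(pi[yi == i], pi[yi == j])
        a_ji = brute_force_auc(pj[yi == j], pj[yi == i])
        pair_vals.append((a_ij + a_ji) / 2)
    return float(np.mean(pair_vals))


class TestConfusionMatrix:
    def test_perfect_predictions_diagonal(self):
        y = np.array([0, 1, 2, 2, 1])
        m = confusion_matrix(y, y, 3)
        np.testing.assert_array_equal(m, np.diag([1, 2, 2]))

    def test_hand_counted_example(self):
        m = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        np.testing.assert_array_equal(m, [[1, 1], [0, 1]])
        norm, flagged = normalize_confusion(m)
        np.testing.assert_allclose(norm, [[0.5, 0.5], [0.0, 1.0]])
        assert flagged == []

    def test_total_count_conservation(self, rng):
        for _ in range(10):
            n = int(rng.integers(1, 200))
            y = rng.integers(0, 6, n)
            p = rng.integers(0, 6, n)
            assert confusion_matrix(y, p, 6).sum() == n

    def test_out_of_range_labels_rejected(self):
        with pytest.raises(ValueError):
            confusion_matrix([0, 7], [0, 1], 6)

    def test_zero_support_row_flagged(self):
        m = confusion_matrix([0, 0], [0, 1], 3)
        norm, flagged = normalize_confusion(m)
        assert flagged == [1, 2]
        np.testing.assert_allclose(norm.sum(axis=1)[:1], 1.0)


class TestMacroMetrics:
    def test_perfect_predictions_all_ones(self):
        m = confusion_matrix([0, 1, 2], [0, 1, 2], 3)
        r = macro_metrics(m)
        for k in ("accuracy", "macro_precision", "macro_recall", "macro_f1"):
            assert r[k] == 1.0

    def test_hand_evaluated_two_class_example(self):
        # true (0,0,1), predicted (0,1,1)
        m = confusion_matrix([0, 0, 1], [0, 1, 1], 2)
        r = macro_metrics(m)
        assert r["accuracy"] == pytest.approx(2 / 3, abs=1e-12)
        assert r["macro_precision"] == pytest.approx(0.75, abs=1e-12)
        assert r["macro_recall"] == pytest.approx(0.75, abs=1e-12)
        assert r["macro_f1"] == pytest.approx(2 / 3, abs=1e-12)

    def test_agreement_with_reference_implementation(self, rng):
        """100 random label sets vs scikit-learn, 1e-9."""
        from sklearn.metrics import precision_recall_fscore_support

        for _ in range(100):
            n = int(rng.integers(5, 30))
            y = rng.integers(0, 4, n)
            p = rng.integers(0, 4, n)
            r = macro_metrics(confusion_matrix(y, p, 4))
            prec, rec, f1, _ = precision_recall_fscore_support(
                y, p, labels=range(4), average="macro", zero_division=0
            )
            assert r["macro_precision"] == pytest.approx(prec, abs=1e-9)
            assert r["macro_recall"] == pytest.approx(rec, abs=1e-9)
            assert r["macro_f1"] == pytest.approx(f1, abs=1e-9)
            assert r["accuracy"] == pytest.approx((y == p).mean(), abs=1e-9)

    def test_relabeling_invariance(self, rng):
        y = rng.integers(0, 5, 40)
        p = rng.integers(0, 5, 40)
        perm = rng.permutation(5)
        a = macro_metrics(confusion_matrix(y, p, 5))
        b = macro_metrics(confusion_matrix(perm[y], perm[p], 5))
        for k in ("accuracy", "macro_precision", "macro_recall", "macro_f1"):
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_zero_predicted_class_flagged_as_zero(self):
        m = confusion_matrix([0, 1], [0, 0], 2)
        r = macro_metrics(m)
        assert 1 in r["zero_division_flags"]
        assert r["per_class_precision"][1] == 0.0


class TestMacroAucOvo:
    def test_perfect_separation_gives_one(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        probs = np.eye(3)[y] * 0.8 + 0.1
        probs /= probs.sum(axis=1, keepdims=True)
        auc, skipped = macro_auc_ovo(y, probs)
        assert auc == pytest.approx(1.0)
        assert skipped == []

    def test_label_independent_probabilities_give_half(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        probs = np.full((6, 3), 1 / 3)
        auc, _ = macro_auc_ovo(y, probs)
        assert auc == pytest.approx(0.5)  # ties count 1/2

    def test_toy_table_matches_exhaustive_enumeration(self):
        """3-class, 6-sample table vs brute-force Mann-Whitney pairs."""
        y = np.array([0, 0, 1, 1, 2, 2])
        probs = np.array(
            [
                [0.6, 0.3, 0.1],
                [0.4, 0.4, 0.2],
                [0.3, 0.5, 0.2],
                [0.5, 0.3, 0.2],
                [0.2, 0.3, 0.5],
                [0.1, 0.2, 0.7],
            ]
        )
        auc, _ = macro_auc_ovo(y, probs)
        assert auc == pytest.approx(brute_force_ovo(y, probs), abs=1e-12)

    def test_random_tables_match_brute_force(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 30))
            y = rng.integers(0, 4, n)
            probs = rng.dirichlet(np.ones(4), size=n)
            ours, _ = macro_auc_ovo(y, probs)
            ref = brute_force_ovo(y, probs)
            if np.isnan(ours):
                continue
            assert ours == pytest.approx(ref, abs=1e-9)

    def test_binary_reduces_to_ordinary_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        y = rng.integers(0, 2, 25)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        p1 = rng.random(25)
        probs = np.stack([1 - p1, p1], axis=1)
        ours, _ = macro_auc_ovo(y, probs)
        assert ours == pytest.approx(roc_auc_score(y, p1), abs=1e-12)

    def test_missing_pair_skipped_and_flagged(self):
        y = np.array([0, 0, 1, 1])  # class 2 absent
        probs = np.full((4, 3), 1 / 3)
        auc, skipped = macro_auc_ovo(y, probs)
        assert set(skipped) == {(0, 2), (1, 2)}
        assert auc == pytest.approx(0.5)


class TestAggregation:
    def test_identical_folds_zero_std(self):
        reps = [_report(0.8) for _ in range(3)]
        tab = aggregate_folds(reps)
        row = tab[tab.metric == "accuracy"].iloc[0]
        assert row["mean"] == pytest.approx(0.8)
        assert row["std"] == pytest.approx(0.0, abs=1e-12)

    def test_two_fold_hand_arithmetic(self):
        tab = aggregate_folds([_report(0.8), _report(0.9)])
        row = tab[tab.metric == "accuracy"].iloc[0]
        assert row["mean"] == pytest.approx(0.85)
        assert row["std"] == pytest.approx(np.sqrt(0.005), abs=1e-9)  # ~0.0707
        assert row["formatted"].startswith("0.8500 ± 0.0707")

    def test_single_fold_flagged(self):
        tab = aggregate_folds([_report(0.7)])
        assert bool(tab.iloc[0]["flagged"])

    def test_mean_within_min_max(self, rng):
        vals = rng.random(5)
        tab = aggregate_folds([_report(v) for v in vals])
        row = tab[tab.metric == "accuracy"].iloc[0]
        assert vals.min() <= row["mean"] <= vals.max()


class TestPairedTTest:
    def test_identical_vectors(self):
        r = paired_ttest([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        assert r["statistic"] == 0.0
        assert r["p_value"] == pytest.approx(1.0)
        assert not r["significant"]

    def test_constant_nonzero_difference_flagged(self):
        r = paired_ttest([0.8, 0.8, 0.8], [0.7, 0.7, 0.7])
        assert r["zero_variance"]
        assert not r["significant"]

    def test_statistic_matches_hand_formula(self, rng):
        a = rng.random(5)
        b = rng.random(5)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        r = paired_ttest(a, b)
        assert r["statistic"] == pytest.approx(t_hand, rel=1e-9)

    def test_too_short_vectors_rejected(self):
        with pytest.raises(ValueError):
            paired_ttest([0.5], [0.4])


class TestEvaluatePredictions:
    def test_full_report_consistency(self, rng):
        n = 60
        y = rng.integers(0, 6, n)
        probs = rng.dirichlet(np.ones(6), size=n)
        rep = evaluate_predictions(y, probs)
        assert rep.confusion.sum() == n
        rows = rep.confusion_normalized.sum(axis=1)
        support = rep.confusion.sum(axis=1)
        np.testing.assert_allclose(rows[support > 0], 1.0, atol=1e-9)
        for m in rep.METRICS[:-1]:
            assert 0.0 <= getattr(rep, m) <= 1.0

    def test_comparison_table_identical_variants_not_flagged(self):
        reps = {
            "a": [_report(0.8), _report(0.82), _report(0.81)],
            "b": [_report(0.8), _report(0.82), _report(0.81)],
        }
        tab = comparison_table(reps, reference="a")
        assert not any("*" in v for v in tab[tab.model == "b"].iloc[0][1:])


def _report(acc):
    """Minimal EvalReport with every metric set to ``acc``."""
    import pandas as pd
    from ocufusion.evaluation import EvalReport

    return EvalReport(
        accuracy=acc,
        macro_precision=acc,
        macro_recall=acc,
        macro_f1=acc,
        macro_auc=acc,
        confusion=np.eye(2, dtype=np.int64),
        confusion_normalized=np.eye(2),
        per_class=pd.DataFrame(),
    )
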