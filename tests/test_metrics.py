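"""Metric definitions, definition gaps, and the composite metric's totality."""

import math

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef

from mism import (
    BinaryMask,
    MetricConfig,
    accuracy,
    counts_from_cells,
    dsc,
    evaluate_all,
    fpr,
    mism,
    nmcc,
    specificity,
    weighted_specificity,
)

TOL = 5e-5  # printed 4-decimal values
PAPER = counts_from_cells(0, 5000, 55000, 0)  # worked example: N=60000, P=0


class TestDice:
    @pytest.mark.parametrize(
        "cells, expected",
        [
            ((100, 0, 0, 0), 1.0),      # perfect positive prediction
            ((0, 5000, 55000, 0), 0.0),  # weak label with FP: pinned at zero
            ((1, 1, 0, 1), 0.5),         # 2/(2+1+1)
        ],
    )
    def test_values(self, cells, expected):
        assert dsc(counts_from_cells(*cells)).value == pytest.approx(expected, abs=TOL)

    def test_undefined_for_fully_true_negative_prediction(self):
        r = dsc(counts_from_cells(0, 0, 9, 0))
        assert not r.defined


class TestFprAndSpecificity:
    def test_paper_counts(self):
        assert fpr(PAPER).value == pytest.approx(5000 / 60000, abs=TOL)
        assert specificity(PAPER).value == pytest.approx(0.9167, abs=TOL)

    def test_everything_wrong_gives_fpr_one(self):
        assert fpr(counts_from_cells(0, 6, 0, 0)).value == 1.0

    def test_undefined_without_actual_negatives(self):
        c = counts_from_cells(3, 0, 0, 2)
        assert not fpr(c).defined
        assert not specificity(c).defined
        assert not specificity(counts_from_cells(4, 0, 0, 1)).defined

    def test_spec_complements_fpr(self, enumerate_small_counts):
        for c in enumerate_small_counts():
            s, f = specificity(c), fpr(c)
            assert s.defined == f.defined
            if s.defined:
                assert s.value == pytest.approx(1.0 - f.value, abs=1e-12)


class TestWeightedSpecificity:
    def test_paper_worked_example(self):
        r = weighted_specificity(PAPER, MetricConfig(alpha=0.1))
        assert r.value == pytest.approx(0.55, abs=1e-12)
        assert r.alpha_used == 0.1

    def test_no_false_positives_scores_one(self):
        for alpha in (0.05, 0.1, 0.9):
            r = weighted_specificity(counts_from_cells(0, 0, 60000, 0), MetricConfig(alpha))
            assert r.value == 1.0

    def test_alpha_half_reduces_to_specificity(self, enumerate_small_counts):
        cfg = MetricConfig(alpha=0.5)
        for c in enumerate_small_counts():
            if c.n > 0:
                assert weighted_specificity(c, cfg).value == pytest.approx(
                    specificity(c).value, abs=1e-12
                )

    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.1, 1.5])
    def test_alpha_endpoints_rejected(self, alpha):
        with pytest.raises(ValueError, match="alpha"):
            MetricConfig(alpha=alpha)


class TestMism:
    def test_weak_label_branch_matches_weighted_specificity(self):
        cfg = MetricConfig(alpha=0.1)
        assert mism(PAPER, cfg).value == weighted_specificity(PAPER, cfg).value == 0.55

    def test_perfect_weak_label_prediction_scores_one(self):
        assert mism(counts_from_cells(0, 0, 60000, 0), MetricConfig(0.1)).value == 1.0

    def test_positive_branch_is_dice_bitwise(self, enumerate_small_counts):
        cfg = MetricConfig(alpha=0.1)
        for c in enumerate_small_counts():
            if c.p > 0:
                assert mism(c, cfg).value == dsc(c).value  # identical float

    def test_total_where_dsc_and_spec_have_gaps(self, enumerate_small_counts):
        """Exhaustive enumeration of cells in 0..6: MISm is defined everywhere,
        DSC is undefined exactly when TP=FP=FN=0, Spec exactly when TN=FP=0."""
        cfg = MetricConfig(alpha=0.1)
        for c in enumerate_small_counts():
            assert mism(c, cfg).defined
            assert dsc(c).defined == (c.tp + c.fp + c.fn > 0)
            assert specificity(c).defined == (c.tn + c.fp > 0)

    def test_strictly_decreasing_in_fp_on_weak_labels(self):
        n = 50
        cfg = MetricConfig(alpha=0.1)
        values = [mism(counts_from_cells(0, fp, n - fp, 0), cfg).value for fp in range(n + 1)]
        assert values[0] == 1.0 and values[-1] == 0.0
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_strictly_increasing_in_alpha_for_fixed_weak_label_errors(self):
        alphas = [0.01, 0.1, 0.3, 0.5, 0.7, 0.99]
        values = [mism(PAPER, MetricConfig(a)).value for a in alphas]
        assert all(a < b for a, b in zip(values, values[1:]))


class TestNmcc:
    def test_inverted_annotation_scores_zero(self):
        assert nmcc(counts_from_cells(0, 40, 0, 20)).value == 0.0

    def test_perfect_prediction_scores_one(self):
        assert nmcc(counts_from_cells(10, 0, 50, 0)).value == 1.0

    def test_weak_label_errors_collapse_to_half(self):
        assert nmcc(PAPER).value == 0.5

    def test_matches_sklearn_mcc_on_random_masks(self, rng):
        from mism import compute_confusion, mcc

        for _ in range(25):
            t = rng.random(30) < 0.4
            q = rng.random(30) < 0.4
            c = compute_confusion(BinaryMask(t.reshape(5, 6)), BinaryMask(q.reshape(5, 6)))
            marginals = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
            if marginals == 0:
                assert mcc(c) == 0.0
            else:
                assert mcc(c) == pytest.approx(
                    matthews_corrcoef(t.astype(int), q.astype(int)), abs=1e-10
                )


class TestAccuracyAndRanges:
    def test_paper_counts(self):
        assert accuracy(PAPER).value == pytest.approx(55000 / 60000, abs=TOL)

    def test_extremes(self):
        assert accuracy(counts_from_cells(3, 0, 5, 0)).value == 1.0
        assert accuracy(counts_from_cells(0, 2, 0, 2)).value == 0.0

    def test_every_defined_metric_in_unit_interval(self, enumerate_small_counts):
        cfg = MetricConfig(alpha=0.1)
        for c in enumerate_small_counts():
            for r in (dsc(c), fpr(c), specificity(c),
                      weighted_specificity(c, cfg), mism(c, cfg),
                      accuracy(c), nmcc(c)):
                if r.defined:
                    assert 0.0 <= r.value <= 1.0


class TestEvaluateAll:
    def mask(self, rows):
        return BinaryMask(np.array(rows, dtype=bool))

    def test_identical_nonempty_masks_score_perfectly(self):
        m = self.mask([[1, 0], [0, 1]])
        by_name = {r.name: r for r in evaluate_all(m, m)}
        for name in ("DSC", "Spec", "wSpec", "Acc", "nMCC", "MISm"):
            assert by_name[name].value == 1.0
        assert by_name["FPR"].value == 0.0

    def test_empty_truth_and_prediction(self):
        m = BinaryMask(np.zeros((3, 3), bool))
        by_name = {r.name: r for r in evaluate_all(m, m)}
        assert by_name["MISm"].value == 1.0
        assert by_name["wSpec"].value == 1.0
        assert by_name["Spec"].value == 1.0
        assert by_name["Acc"].value == 1.0
        assert not by_name["DSC"].defined

    def test_complement_prediction_with_both_classes(self):
        m = self.mask([[1, 1], [0, 0]])
        by_name = {r.name: r for r in evaluate_all(m, m.complement())}
        assert by_name["DSC"].value == 0.0
        assert by_name["Acc"].value == 0.0
        assert by_name["nMCC"].value == 0.0

    def test_hand_enumerated_pair(self):
        truth = self.mask([[1, 1], [0, 0]])
        pred = self.mask([[1, 0], [1, 0]])
        by_name = {r.name: r for r in evaluate_all(truth, pred)}
        assert by_name["DSC"].value == 0.5
        assert by_name["Acc"].value == 0.5
        assert by_name["MISm"].value == 0.5

    def test_all_results_share_one_confusion_matrix(self):
        truth = self.mask([[1, 0], [0, 0]])
        pred = self.mask([[0, 1], [0, 0]])
        results = evaluate_all(truth, pred)
        assert len({id(r.counts) for r in results}) == 1
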