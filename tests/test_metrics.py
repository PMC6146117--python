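"""Evaluation metrics against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from humtag import (AgreementTable, agreement_stats, auc, binarize,
                    binary_metrics, brier, calibration_adjusted_r2,
                    calibration_curve, evaluate, score_histogram)
from humtag.metrics import ConfusionTable


def brute_force_auc(scores, labels):
    """Independent oracle: enumerate all positive-negative pairs."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAuc:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.9, 0.1], [1, 0], 1.0),
        ([0.8, 0.6, 0.4, 0.2], [1, 0, 1, 0], 0.75),
        ([0.5, 0.5, 0.5], [1, 0, 1], 0.5),   # all ties
    ])
    def test_known_values(self, scores, labels, expected):
        assert auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [True, True])

    @given(st.data())
    @settings(max_examples=300, deadline=None)
    def test_matches_pairwise_oracle(self, data):
        n = data.draw(st.integers(3, 30))
        scores = data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=n, max_size=n))
        labels = data.draw(st.lists(st.booleans(), min_size=n, max_size=n))
        if all(labels) or not any(labels):
            labels[0] = not labels[0]
        assert auc(scores, labels) == pytest.approx(
            brute_force_auc(scores, labels))

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score
        rng = np.random.default_rng(0)
        scores = rng.random(500)
        labels = rng.random(500) < 0.6
        assert auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores))


class TestBinarize:
    def test_boundary_is_positive(self):
        t = binarize([0.50], [True], threshold=0.50)
        assert t.tp == 1 and t.fn == 0

    def test_threshold_zero_all_positive(self):
        t = binarize([0.0, 0.3, 1.0], [True, False, True], threshold=0.0)
        assert t.tp + t.fp == 3

    def test_all_correct(self):
        t = binarize([1.0] * 4, [True] * 4)
        assert t.tp == 4 and t.fp == t.tn == t.fn == 0


class TestBinaryMetrics:
    def test_perfect(self):
        m = binary_metrics(ConfusionTable(tp=5, fp=0, tn=5, fn=0))
        assert (m.mcc, m.f1, m.error_rate) == (1.0, 1.0, 0.0)

    def test_numerator_cancels(self):
        m = binary_metrics(ConfusionTable(tp=1, fp=1, tn=1, fn=1))
        assert m.mcc == 0.0
        assert m.f1 == pytest.approx(0.5)
        assert m.error_rate == pytest.approx(0.5)

    def test_hand_computed_table(self):
        # tp=90 fn=10 fp=5 tn=95, arithmetic done by hand:
        # P=90/95, R=90/100, F1=2PR/(P+R)=180/195,
        # MCC=(90*95-5*10)/sqrt(95*100*100*105)
        m = binary_metrics(ConfusionTable(tp=90, fp=5, tn=95, fn=10))
        assert m.precision == pytest.approx(90 / 95)
        assert m.recall == pytest.approx(0.9)
        assert m.f1 == pytest.approx(180 / 195)
        assert m.mcc == pytest.approx(
            (90 * 95 - 5 * 10) / np.sqrt(95 * 100 * 100 * 105))
        assert m.error_rate == pytest.approx(15 / 200)

    def test_zero_marginal_convention(self):
        m = binary_metrics(ConfusionTable(tp=0, fp=0, tn=10, fn=5))
        assert m.mcc == 0.0 and m.precision == 0.0

    def test_mcc_symmetric_f1_not(self):
        # swapping the positive/negative roles transposes the table:
        # MCC is invariant, F1 is not
        t = ConfusionTable(tp=80, fp=10, tn=40, fn=20)
        swapped = ConfusionTable(tp=t.tn, fp=t.fn, tn=t.tp, fn=t.fp)
        assert binary_metrics(t).mcc == pytest.approx(binary_metrics(swapped).mcc)
        assert binary_metrics(t).f1 != pytest.approx(binary_metrics(swapped).f1)


class TestBrier:
    def test_exact_predictions(self):
        assert brier([1.0, 0.0], [True, False]) == 0.0

    def test_constant_half(self):
        assert brier([0.5] * 10, [True] * 5 + [False] * 5) == pytest.approx(0.25)

    def test_hand_value(self):
        assert brier([0.8, 0.3], [1, 0]) == pytest.approx(0.065)

    def test_constant_predictor_closed_form(self):
        # Brier of constant p at prevalence pi is pi(1-p)^2 + (1-pi)p^2,
        # minimized at p = pi
        rng = np.random.default_rng(0)
        labels = rng.random(20000) < 0.65
        pi = labels.mean()
        for p in (0.3, 0.65, 0.9):
            expected = pi * (1 - p) ** 2 + (1 - pi) * p ** 2
            assert brier([p] * len(labels), labels) == pytest.approx(expected)
        best = min((brier([p] * len(labels), labels), p)
                   for p in np.linspace(0, 1, 101))
        assert best[1] == pytest.approx(pi, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            brier([], [])


class TestCalibrationCurve:
    def test_single_populated_bin(self):
        curve = calibration_curve([0.975] * 10, [True] * 10)
        pop = curve.populated()
        assert len(pop) == 1
        assert pop[0].proportion == 1.0
        assert pop[0].lo == pytest.approx(0.95)

    def test_bin_counts_conserved(self):
        rng = np.random.default_rng(1)
        scores = rng.random(1000)
        labels = rng.random(1000) < scores
        curve = calibration_curve(scores, labels)
        assert curve.n == 1000
        assert len(curve.bins) == 20

    def test_score_one_lands_in_top_bin(self):
        curve = calibration_curve([1.0], [True])
        assert curve.bins[-1].n == 1

    def test_bad_bin_width_rejected(self):
        with pytest.raises(ValueError, match="divide"):
            calibration_curve([0.5], [True], bin_width=0.3)

    def test_near_diagonal_for_calibrated_scores(self):
        # labels drawn Bernoulli(score): the curve must hug the diagonal
        rng = np.random.default_rng(2)
        scores = rng.random(20000)
        labels = rng.random(20000) < scores
        curve = calibration_curve(scores, labels)
        for b in curve.bins:
            if b.n >= 100:
                assert abs(b.mean_score - b.proportion) < 0.05


class TestAdjustedR2:
    def test_perfect_fit(self):
        scores = np.repeat(np.linspace(0.05, 0.95, 10), 20)
        labels = np.tile([True, False], 100)
        curve = calibration_curve(scores, scores >= 0.5)
        # proportions are exactly 0 or 1 step; instead build an exactly
        # linear relationship: proportion equals mean score per bin
        from humtag.metrics import CalibrationBin, CalibrationCurve
        bins = tuple(CalibrationBin(lo=i * 0.1, hi=(i + 1) * 0.1, n=10,
                                    mean_score=0.05 + 0.1 * i,
                                    proportion=0.05 + 0.1 * i)
                     for i in range(10))
        assert calibration_adjusted_r2(
            CalibrationCurve(bins=bins, bin_width=0.1)) == pytest.approx(1.0)

    def test_constant_proportions_not_explained(self):
        from humtag.metrics import CalibrationBin, CalibrationCurve
        bins = tuple(CalibrationBin(lo=i * 0.2, hi=(i + 1) * 0.2, n=10,
                                    mean_score=0.1 + 0.2 * i, proportion=0.5)
                     for i in range(5))
        assert calibration_adjusted_r2(
            CalibrationCurve(bins=bins, bin_width=0.2)) <= 0.0

    def test_five_bin_hand_dataset(self):
        # closed-form least squares on (x, y) pairs computed by hand
        from humtag.metrics import CalibrationBin, CalibrationCurve
        x = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        y = np.array([0.15, 0.25, 0.55, 0.65, 0.95])
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        ss_res = np.sum((y - slope * x - intercept) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        expected = 1 - (1 - (1 - ss_res / ss_tot)) * 4 / 3
        bins = tuple(CalibrationBin(lo=i * 0.2, hi=(i + 1) * 0.2, n=10,
                                    mean_score=float(xi), proportion=float(yi))
                     for i, (xi, yi) in enumerate(zip(x, y)))
        assert calibration_adjusted_r2(
            CalibrationCurve(bins=bins, bin_width=0.2)) == pytest.approx(expected)

    def test_too_few_bins_rejected(self):
        curve = calibration_curve([0.1, 0.9], [False, True])
        with pytest.raises(ValueError, match="3 populated"):
            calibration_adjusted_r2(curve)


class TestScoreHistogram:
    def test_all_positives_in_top_bin(self):
        h = score_histogram([0.99] * 10 + [0.1] * 5,
                            [True] * 10 + [False] * 5)
        assert h.positive_pct[-1] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(3)
        scores = rng.random(500)
        labels = rng.random(500) < 0.6
        h = score_histogram(scores, labels)
        assert h.positive_pct.sum() == pytest.approx(100.0)
        assert h.negative_pct.sum() == pytest.approx(100.0)

    def test_high_separation_mass_at_extremes(self, trained_tagger,
                                              split_small):
        _, test_c, y, _ = split_small
        scores = trained_tagger.tag_corpus(test_c)
        h = score_histogram(scores, y)
        outer_pos = h.positive_pct[-2:].sum() + h.positive_pct[:2].sum()
        outer_neg = h.negative_pct[-2:].sum() + h.negative_pct[:2].sum()
        assert outer_pos > 80.0
        assert outer_neg > 80.0


class TestAgreementStats:
    def test_review_table_strata(self):
        # 2x3 review-count table: each stratum's agreement is the count
        # matching the model's side over the row total
        stats = agreement_stats(AgreementTable(low=(2, 97, 1),
                                               high=(50, 41, 9)))
        assert stats.low_pct == pytest.approx(97.0)
        assert stats.high_pct == pytest.approx(50.0)
        assert stats.overall_pct == pytest.approx(73.5)

    def test_uncertain_counts_as_disagreement(self):
        stats = agreement_stats(AgreementTable(low=(0, 5, 5), high=(5, 0, 5)))
        assert stats.low_pct == 50.0
        assert stats.high_pct == 50.0
        assert stats.overall_pct == 50.0

    def test_empty_stratum_rejected(self):
        with pytest.raises(ValueError):
            agreement_stats(AgreementTable(low=(0, 0, 0), high=(1, 1, 1)))


class TestEvaluate:
    def test_report_fields_within_bounds(self, trained_tagger, split_small):
        _, test_c, y, _ = split_small
        scores = trained_tagger.tag_corpus(test_c)
        rep = evaluate(scores, y)
        assert 0 <= rep.auc <= 1 and -1 <= rep.mcc <= 1
        assert 0 <= rep.brier <= 1 and 0 <= rep.error_rate <= 1
        assert rep.n == len(y) and rep.threshold == 0.50
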