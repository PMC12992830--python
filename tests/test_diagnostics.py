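"""Confusion metrics, rank AUC, DeLong, threshold sweep, correlations."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barriertox.diagnostics import (ConfusionCounts, EvaluationError,
                                    classify_by_reduction, confusion,
                                    correlation_matrix, delong_ci,
                                    evaluate_assay, mann_whitney_p, metrics,
                                    pearson_r, rank_auc, threshold_sweep)
from barriertox.scoring import reference_labels


def pair_count_auc(scores, labels):
    """Exhaustive positive-negative pair counting (independent oracle)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestClassifyByReduction:
    @pytest.mark.parametrize("reduction,expected", [
        (89.51, True),   # paclitaxel hIEC TEER
        (49.84, False),  # ketoprofen hIEC TEER, just below
        (50.0, True),    # inclusive boundary
    ])
    def test_inclusive_cutoff(self, reduction, expected):
        assert classify_by_reduction(reduction) is expected


class TestConfusion:
    def test_hiec_teer_counts(self, panel):
        labels = reference_labels(panel)
        summaries = panel.summaries_for("hIEC", "TEER")
        counts = confusion([s.pct_reduction >= 50 for s in summaries],
                           [labels[s.drug] for s in summaries])
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (11, 1, 5, 0)

    def test_caco2_teer_counts(self, panel):
        labels = reference_labels(panel)
        summaries = panel.summaries_for("Caco-2", "TEER")
        counts = confusion([s.pct_reduction >= 50 for s in summaries],
                           [labels[s.drug] for s in summaries])
        assert (counts.tp, counts.fn, counts.tn, counts.fp) == (10, 2, 3, 2)

    def test_perfect_predictions(self):
        counts = confusion([True, True, False], [True, True, False])
        assert counts.fp == counts.fn == 0

    def test_single_class_labels_rejected(self):
        with pytest.raises(EvaluationError):
            confusion([True, False], [True, True])


class TestMetrics:
    def test_hiec_teer_rates(self):
        rep = metrics(ConfusionCounts(tp=11, fn=1, tn=5, fp=0))
        assert rep.sensitivity == pytest.approx(11 / 12)
        assert rep.specificity == 1.0
        assert rep.accuracy == pytest.approx(16 / 17)
        assert rep.youden_j == pytest.approx(11 / 12 + 1.0 - 1.0)

    def test_caco2_teer_rates(self):
        rep = metrics(ConfusionCounts(tp=10, fn=2, tn=3, fp=2))
        assert rep.sensitivity == pytest.approx(10 / 12)
        assert rep.specificity == pytest.approx(0.6)
        assert rep.accuracy == pytest.approx(13 / 17)

    def test_undefined_rates_flagged_not_coerced(self):
        rep = metrics(ConfusionCounts(tp=0, fn=0, tn=3, fp=2))
        assert math.isnan(rep.sensitivity)
        assert "sensitivity" in rep.undefined

    @given(tp=st.integers(0, 20), tn=st.integers(0, 20),
           fp=st.integers(0, 20), fn=st.integers(0, 20))
    @settings(max_examples=100, deadline=None)
    def test_j_and_accuracy_identities(self, tp, tn, fp, fn):
        counts = ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)
        if counts.n == 0:
            return
        rep = metrics(counts)
        if not math.isnan(rep.youden_j):
            assert rep.youden_j == rep.sensitivity + rep.specificity - 1.0
        assert rep.accuracy == pytest.approx((tp + tn) / counts.n)


class TestRankAuc:
    def test_bundled_binarized_decisions(self, panel):
        labels = reference_labels(panel)
        summaries = panel.summaries_for("hIEC", "TEER")
        lab = [labels[s.drug] for s in summaries]
        decisions = [1.0 if s.pct_reduction >= 50 else 0.0 for s in summaries]
        assert rank_auc(decisions, lab) == pytest.approx(0.9583, abs=1e-4)

    def test_bundled_continuous_reductions(self, panel):
        labels = reference_labels(panel)
        summaries = panel.summaries_for("hIEC", "TEER")
        lab = [labels[s.drug] for s in summaries]
        scores = [s.pct_reduction for s in summaries]
        assert rank_auc(scores, lab) == pytest.approx(56 / 60, rel=1e-12)

    def test_perfect_separation(self):
        assert rank_auc([3, 4, 5, 1, 2], [True, True, True, False, False]) == 1.0

    @given(st.lists(st.tuples(st.integers(0, 5), st.booleans()),
                    min_size=2, max_size=20))
    @settings(max_examples=300, deadline=None)
    def test_matches_pair_counting_oracle(self, data):
        scores = [float(s) for s, _ in data]
        labels = [l for _, l in data]
        if all(labels) or not any(labels):
            return
        assert rank_auc(scores, labels) == pytest.approx(
            pair_count_auc(scores, labels), rel=1e-12)

    def test_binary_decisions_reduce_to_sens_spec_average(self):
        """Exhaustive over all binary prediction/label patterns n <= 6."""
        for n in range(2, 7):
            for lab_bits in itertools.product([False, True], repeat=n):
                if all(lab_bits) or not any(lab_bits):
                    continue
                for pred_bits in itertools.product([0.0, 1.0], repeat=n):
                    preds = [p >= 0.5 for p in pred_bits]
                    counts = confusion(preds, lab_bits)
                    rep = metrics(counts)
                    expected = (rep.sensitivity + rep.specificity) / 2.0
                    assert rank_auc(pred_bits, lab_bits) == pytest.approx(
                        expected, rel=1e-12)


class TestDelongCi:
    def test_matches_reference_roc_implementation(self):
        """Frozen oracle values computed with the pROC DeLong routine
        (roc/ci.auc, direction '<') on this fixed 8v6 dataset."""
        labels = [True] * 8 + [False] * 6
        scores = [2.3, 1.1, 3.5, 0.7, 2.9, 1.8, 2.2, 0.9,
                  0.4, 1.5, 0.8, 1.2, 0.3, 1.0]
        from barriertox.diagnostics import delong_variance
        assert rank_auc(scores, labels) == pytest.approx(0.8125, abs=1e-12)
        assert delong_variance(scores, labels) == pytest.approx(
            0.014310515873, abs=1e-10)
        lo, hi, degen = delong_ci(scores, labels)
        assert lo == pytest.approx(0.578036234294, abs=1e-9)
        assert hi == 1.0  # truncated to [0, 1]
        assert not degen

    def test_perfect_separation_degenerate(self):
        lo, hi, degen = delong_ci([2, 3, 4, 0, 1], [True, True, True, False, False])
        assert degen
        assert (lo, hi) == (1.0, 1.0)

    def test_bundled_hiec_teer_upper_bound_capped(self, panel):
        labels = reference_labels(panel)
        summaries = panel.summaries_for("hIEC", "TEER")
        lab = [labels[s.drug] for s in summaries]
        decisions = [1.0 if s.pct_reduction >= 50 else 0.0 for s in summaries]
        lo, hi, _ = delong_ci(decisions, lab)
        assert hi == 1.0
        assert 0.7 < lo < 0.96

    def test_monte_carlo_coverage(self):
        """Seeded binormal experiment (true AUC 0.8, n=200): the 95%
        DeLong interval covers truth at ~95% over 1,000 replicates."""
        from scipy import stats as ss
        mu = math.sqrt(2) * ss.norm.ppf(0.8)
        rng = np.random.default_rng(2026)
        cover = 0
        B = 1000
        for _ in range(B):
            pos = rng.normal(mu, 1, 100)
            neg = rng.normal(0.0, 1, 100)
            scores = np.concatenate([pos, neg])
            lab = np.array([True] * 100 + [False] * 100)
            lo, hi, _ = delong_ci(scores, lab)
            cover += lo <= 0.8 <= hi
        assert 0.93 <= cover / B <= 0.97


class TestMannWhitney:
    def test_all_tied_scores_no_evidence(self):
        assert mann_whitney_p([1.0] * 6, [True] * 3 + [False] * 3) == 1.0

    def test_perfect_separation_significant(self):
        scores = list(range(5, 17)) + list(range(5))
        labels = [True] * 12 + [False] * 5
        assert mann_whitney_p(scores, labels) < 0.001

    def test_caco2_atp_decisions_nonsignificant(self, panel):
        labels = reference_labels(panel)
        summaries = panel.summaries_for("Caco-2", "ATP")
        lab = [labels[s.drug] for s in summaries]
        decisions = [1.0 if s.pct_reduction >= 50 else 0.0 for s in summaries]
        assert mann_whitney_p(decisions, lab) > 0.05


class TestThresholdSweep:
    def test_hiec_teer_plateau(self, panel):
        labels = reference_labels(panel)
        summaries = panel.summaries_for("hIEC", "TEER")
        curve = threshold_sweep([s.pct_reduction for s in summaries],
                                [labels[s.drug] for s in summaries])
        at50 = int(np.where(curve.cutoffs == 50.0)[0][0])
        assert curve.youden_j[at50] == pytest.approx(11 / 12, abs=1e-9)
        assert curve.accuracy[at50] == pytest.approx(16 / 17, abs=1e-9)
        # high-J plateau spans the 50-65% region
        assert curve.plateau[0] <= 50.0 and curve.plateau[1] >= 65.0

    def test_caco2_plateau_lower_and_later(self, panel):
        labels = reference_labels(panel)
        summaries = panel.summaries_for("Caco-2", "TEER")
        curve = threshold_sweep([s.pct_reduction for s in summaries],
                                [labels[s.drug] for s in summaries])
        assert curve.max_j == pytest.approx(0.75, abs=0.02)
        assert curve.plateau[0] >= 60.0

    def test_cutoff_zero_calls_everything_positive(self, panel):
        labels = reference_labels(panel)
        summaries = panel.summaries_for("hIEC", "TEER")
        curve = threshold_sweep([s.pct_reduction for s in summaries],
                                [labels[s.drug] for s in summaries],
                                grid=[-1000.0])
        assert curve.youden_j[0] == pytest.approx(0.0)  # sens 1, spec 0

    def test_reproduces_composed_operations(self, panel):
        labels = reference_labels(panel)
        summaries = panel.summaries_for("hIEC", "TEER")
        red = [s.pct_reduction for s in summaries]
        lab = [labels[s.drug] for s in summaries]
        curve = threshold_sweep(red, lab)
        for c, j, a in zip(curve.cutoffs, curve.youden_j, curve.accuracy):
            rep = metrics(confusion([classify_by_reduction(r, c) for r in red], lab))
            assert j == pytest.approx(rep.youden_j, abs=1e-12)
            assert a == pytest.approx(rep.accuracy, abs=1e-12)


class TestPearson:
    def test_self_correlation(self):
        assert pearson_r([1.0, 2.0, 4.0], [1.0, 2.0, 4.0]) == pytest.approx(1.0)

    def test_matches_numpy_two_pass(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = 0.4 * x + rng.normal(size=30)
        assert pearson_r(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    @given(xs=st.lists(st.integers(-1000, 1000).map(lambda v: v / 10.0),
                       min_size=3, max_size=30),
           a=st.one_of(st.floats(-5, -0.01), st.floats(0.01, 5)),
           b=st.floats(-50, 50))
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance_with_sign_flip(self, xs, a, b):
        if len(set(xs)) < 2:
            return
        rng = np.random.default_rng(1)
        ys = list(rng.normal(size=len(xs)))
        base = pearson_r(xs, ys)
        transformed = pearson_r([a * x + b for x in xs], ys)
        assert transformed == pytest.approx(math.copysign(1, a) * base,
                                            abs=1e-7)

    def test_zero_variance_flagged(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelationMatrix:
    def test_printed_entries(self, panel):
        corr = correlation_matrix(panel)
        assert corr.entry("hIEC TEER", "GI toxicity score") == pytest.approx(0.64, abs=0.005)
        assert corr.entry("Caco-2 TEER", "GI toxicity score") == pytest.approx(0.58, abs=0.005)
        assert corr.entry("hIEC ATP", "GI toxicity score") == pytest.approx(0.25, abs=0.005)
        assert corr.entry("Caco-2 ATP", "GI toxicity score") == pytest.approx(-0.04, abs=0.005)

    def test_symmetric_unit_diagonal(self, panel):
        m = correlation_matrix(panel).matrix
        assert np.allclose(m.values, m.values.T)
        assert np.allclose(np.diag(m.values), 1.0)


class TestEvaluateAssay:
    def test_reduction_rule_hiec_teer(self, panel):
        rep = evaluate_assay(panel, "hIEC", "TEER")
        assert rep.accuracy == pytest.approx(16 / 17)
        assert rep.auc == pytest.approx(0.958, abs=0.005)
        assert rep.auc_continuous == pytest.approx(56 / 60, rel=1e-9)
        assert rep.p_value < 0.001

    def test_mos15_rule_hiec_teer(self, panel):
        rep = evaluate_assay(panel, "hIEC", "TEER", "mos15")
        assert rep.sensitivity == pytest.approx(7 / 12)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(11 / 17)

    def test_reduction_rule_caco2_atp(self, panel):
        rep = evaluate_assay(panel, "Caco-2", "ATP")
        assert rep.auc == pytest.approx(0.608, abs=0.005)
        assert rep.p_value > 0.05

    def test_unknown_rule(self, panel):
        with pytest.raises(ValueError, match="unknown rule"):
            evaluate_assay(panel, "hIEC", "TEER", "magic")

    def test_determinism(self, panel):
        a = evaluate_assay(panel, "hIEC", "TEER").to_dict()
        b = evaluate_assay(panel, "hIEC", "TEER").to_dict()
        assert a == b
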