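"""ROC/AUC machinery, operating points, selection rule and test statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from geudpred.eud import build_metric_matrix
from geudpred.roc import (
    DegenerateInputWarning,
    UndefinedStatisticError,
    auc_matrix,
    independent_t,
    paired_t,
    pearson_r,
    roc_auc,
    scan_point_parameters,
    select_optimal_a,
    youden_cutoff,
)
from geudpred.synth import STRUCTURE_BRAIN
from helpers import brute_force_youden, pair_count_auc, random_scores_labels


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([1.0, 2.0], [0, 1]).auc == 1.0

    def test_tie_corrected_pair_probability(self):
        # 3.5 concordant-equivalents of 4 positive x negative pairs
        s = roc_auc([1.0, 2.0, 2.0, 3.0], [0, 0, 1, 1])
        assert s.auc == pytest.approx(0.875, abs=0)
        assert s.auc == pytest.approx(pair_count_auc([1, 2, 2, 3], [0, 0, 1, 1]))

    def test_constant_scores_flagged_half(self):
        with pytest.warns(DegenerateInputWarning):
            s = roc_auc([5.0, 5.0, 5.0], [0, 1, 1])
        assert s.auc == 0.5 and s.degenerate

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            roc_auc([1.0, 2.0], [1, 1])

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_matches_brute_force_pair_counting(self, seed):
        scores, labels = random_scores_labels(np.random.default_rng(seed))
        got = auc_matrix(scores, labels)[0]
        expect = pair_count_auc(scores, labels)
        if math.isnan(got):  # constant scores: oracle gives 0.5
            assert expect == 0.5
        else:
            assert got == pytest.approx(expect, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_invariant_under_increasing_transform(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.normal(60, 6, size=25)
        labels = rng.integers(0, 2, size=25)
        labels[:2] = [0, 1]
        base = roc_auc(scores, labels).auc
        assert roc_auc(np.exp(scores / 20.0), labels).auc == pytest.approx(base, abs=1e-12)
        assert roc_auc(3.0 * scores - 7.0, labels).auc == pytest.approx(base, abs=1e-12)

    def test_delong_ci_matches_pROC_reference(self):
        # frozen output of R pROC ci.auc(..., method="delong") on this fixture
        scores = [61, 64, 59, 70, 66, 58, 72, 63, 65, 60,
                  67, 62, 68, 57, 69, 61, 64, 73, 56, 66]
        labels = [0, 1, 0, 1, 1, 0, 1, 0, 1, 0, 1, 0, 1, 0, 1, 1, 0, 1, 0, 0]
        s = roc_auc(np.array(scores, float), labels)
        assert s.auc == pytest.approx(0.925, abs=1e-12)
        assert s.ci95[0] == pytest.approx(0.813264861537, abs=1e-9)
        assert s.ci95[1] == pytest.approx(1.0, abs=1e-12)

    def test_ci_brackets_auc_and_degenerate_when_perfect(self):
        s = roc_auc([1.0, 2.0, 3.0, 10.0, 11.0], [0, 0, 0, 1, 1])
        assert s.auc == 1.0 and s.degenerate and s.ci95 == (1.0, 1.0)
        s2 = roc_auc(np.arange(10.0), [0, 1, 0, 1, 0, 1, 0, 1, 0, 1])
        assert s2.ci95[0] <= s2.auc <= s2.ci95[1]


class TestYouden:
    def test_j_identity_from_operating_point(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(60, 5, 40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        s = youden_cutoff(scores, labels)
        assert s.youden_j == s.sensitivity + s.specificity - 1.0

    def test_perfect_separation_reaches_j_one(self):
        s = youden_cutoff([1.0, 2.0, 8.0, 9.0], [0, 0, 1, 1])
        assert s.youden_j == pytest.approx(1.0)
        assert 2.0 < s.cutoff < 8.0

    def test_exhaustive_scan_with_lower_cutoff_tie_break(self):
        s = youden_cutoff([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        cutoff, j = brute_force_youden([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        assert s.youden_j == pytest.approx(j) == pytest.approx(0.5)
        assert s.cutoff == pytest.approx(cutoff) == pytest.approx(1.5)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 100_000))
    def test_matches_brute_force_threshold_scan(self, seed):
        scores, labels = random_scores_labels(np.random.default_rng(seed))
        if np.ptp(scores) == 0:
            return
        s = youden_cutoff(scores, labels)
        cutoff, j = brute_force_youden(scores, labels)
        assert s.youden_j == pytest.approx(j, abs=1e-12)
        assert s.cutoff == pytest.approx(cutoff)


class TestSelectOptimalA:
    def test_unique_argmax(self):
        a = np.arange(1.0, 30.5, 0.5)
        aucs = -((a - 21.5) ** 2)
        assert select_optimal_a(a, aucs) == 21.5

    def test_full_grid_tie_resolves_to_median(self):
        a = np.arange(1.0, 30.5, 0.5)
        assert a.size == 59
        assert select_optimal_a(a, np.full(a.size, 0.7)) == 15.5

    def test_even_tie_set_midpoint(self):
        assert select_optimal_a([1.0, 2.0, 3.0], [0.9, 0.9, 0.5]) == 1.5

    def test_result_stays_within_grid(self):
        rng = np.random.default_rng(0)
        a = np.arange(1.0, 30.5, 0.5)
        for _ in range(20):
            got = select_optimal_a(a, rng.random(a.size))
            assert a[0] <= got <= a[-1]


class TestCorrelationAndTTests:
    def test_pearson_exact_lines(self):
        assert pearson_r([1, 2, 3], [3, 5, 7]).r == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [-1, -2, -3]).r == pytest.approx(-1.0)

    def test_pearson_hand_value(self):
        assert pearson_r([1, 2, 3], [1, 3, 2]).r == pytest.approx(0.5)

    def test_pearson_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_r([1, 1, 1], [1, 2, 3])

    def test_paired_identical_flagged(self):
        res = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == 1.0 and res.note

    def test_paired_zero_variance_infinite_t(self):
        res = paired_t([2.0, 3.0, 4.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert math.isinf(res.statistic) and res.statistic > 0 and res.pvalue == 0.0

    def test_paired_hand_value(self):
        res = paired_t([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.statistic == pytest.approx(2.0 * math.sqrt(3.0))

    def test_independent_identical_samples(self):
        res = independent_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.pvalue == pytest.approx(1.0)

    def test_independent_zero_pooled_variance(self):
        res = independent_t([0.0, 0.0], [1.0, 1.0])
        assert math.isinf(res.statistic) and res.statistic < 0

    def test_independent_hand_value(self):
        res = independent_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.statistic == pytest.approx(-math.sqrt(1.5))


class TestScanPointParameters:
    def test_planted_threshold_signal_ranks_first(self, default_cohort):
        cohort, _ = default_cohort
        brains = [o for o in cohort if o.structure == STRUCTURE_BRAIN]
        matrix = build_metric_matrix(brains)
        col = matrix.values["D_2.5cc"].to_numpy()
        labels = (col > np.median(col)).astype(int)
        ranked = scan_point_parameters(matrix, labels)
        assert ranked[0][0].name == "D_2.5cc"
        assert ranked[0][1].auc == 1.0

    def test_constant_columns_score_half(self, default_cohort):
        cohort, _ = default_cohort
        brains = [o for o in cohort if o.structure == STRUCTURE_BRAIN][:20]
        matrix = build_metric_matrix(brains)
        matrix.values.loc[:, :] = 1.0  # flatten every column
        labels = np.zeros(20, dtype=int)
        labels[:7] = 1
        ranked = scan_point_parameters(matrix, labels)
        assert all(s.auc == 0.5 and s.degenerate for _, s in ranked)

    def test_planted_logistic_signal_on_v70(self, default_cohort):
        from scipy.special import expit

        cohort, _ = default_cohort
        brains = [o for o in cohort if o.structure == STRUCTURE_BRAIN]
        matrix = build_metric_matrix(brains)
        v70 = matrix.values["V_70Gy"].to_numpy()
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            z = (v70 - v70.mean()) / v70.std()
            labels = (rng.random(v70.size) < expit(-1.0 + 4.0 * z)).astype(int)
            if labels.min() == labels.max():
                continue
            ranked = scan_point_parameters(matrix, labels)
            top_vd = next(m for m, _ in ranked if m.family == "v_d")
            wins += abs(top_vd.threshold_gy - 70.0) <= 2.0
        assert wins >= 3
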