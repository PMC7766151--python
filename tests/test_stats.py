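"""Cut-off classification, ROC, exact tests, survival."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fetomics.stats import (
    ClassificationMetrics,
    CutoffRule,
    auc,
    classify,
    combine_and,
    fisher_exact,
    km_median,
    log_rank,
    mann_whitney,
    optimal_cutoff,
    survival_arrays,
)


def _frame(pos_vals, neg_vals, parameter="x"):
    return pd.DataFrame(
        {
            "diagnosis": ["PSP"] * len(pos_vals) + ["EP"] * len(neg_vals),
            parameter: list(pos_vals) + list(neg_vals),
        }
    )


class TestClassify:
    def test_all_predicted_positive(self):
        frame = _frame([1, 2], [3, 4])
        m = classify(frame, CutoffRule("x", 100.0, "le"))
        assert m.sensitivity == 1.0 and m.specificity == 0.0

    def test_single_rule_equals_and_of_itself(self, cohort_df):
        rule = CutoffRule("tbr_max", 2.25, "le")
        a = classify(cohort_df, rule)
        b = combine_and(cohort_df, [rule])
        assert (a.tp, a.fp, a.fn, a.tn) == (b.tp, b.fp, b.fn, b.tn)

    def test_undefined_metric_is_none_not_zero(self):
        m = ClassificationMetrics(tp=0, fp=0, fn=0, tn=5)
        assert m.sensitivity is None and m.ppv is None


class TestAUC:
    def test_perfect_separation(self):
        assert auc(_frame([1, 2], [5, 6]), "x", "le") == 1.0

    def test_orientation_flips(self):
        frame = _frame([1, 2], [5, 6])
        assert auc(frame, "x", "ge") == 0.0


class TestOptimalCutoff:
    def test_non_overlapping_groups_midpoint(self):
        frame = _frame([1.0, 2.0], [4.0, 5.0])
        rule = optimal_cutoff(frame, "x", "le")
        assert rule.cutoff == 3.0  # midpoint of the adjacent distinct pair 2, 4

    def test_perfect_auc_implies_perfect_cutoff(self):
        frame = _frame([1.0, 1.5, 2.0], [4.0, 4.5, 5.0])
        assert auc(frame, "x", "le") == 1.0
        m = classify(frame, optimal_cutoff(frame, "x", "le"))
        assert m.sensitivity == 1.0 and m.specificity == 1.0


class TestFisher:
    def test_balanced_table(self):
        assert fisher_exact(((1, 1), (1, 1))) == 1.0

    def test_diagonal_table_exact_value(self):
        # 2 / C(10, 5) = 2/252
        assert fisher_exact(((5, 0), (0, 5))) == pytest.approx(2 / 252, abs=1e-10)

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    @settings(max_examples=40, deadline=None)
    def test_transpose_invariance(self, a, b, c, d):
        assert fisher_exact(((a, b), (c, d))) == pytest.approx(
            fisher_exact(((a, c), (b, d))), abs=1e-12
        )


class TestMannWhitney:
    def test_exact_no_overlap(self):
        assert mann_whitney([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups(self):
        assert mann_whitney([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert mann_whitney(np.ones(12), np.ones(15)) == pytest.approx(1.0)

    def test_matches_scipy_asymptotic_for_large_groups(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1, 25)
        from scipy.stats import mannwhitneyu

        want = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                            use_continuity=False).pvalue
        assert mann_whitney(x, y) == pytest.approx(want)


class TestMCCProperties:
    @given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
    @settings(max_examples=40, deadline=None)
    def test_mcc_invariant_under_joint_label_swap(self, tp, fp, fn, tn):
        m = ClassificationMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
        swapped = ClassificationMetrics(tp=tn, fp=fn, fn=fp, tn=tp)
        if m.mcc is not None:
            assert m.mcc == pytest.approx(swapped.mcc)
            assert -1.0 - 1e-12 <= m.mcc <= 1.0 + 1e-12


class TestCombineAnd:
    @pytest.mark.parametrize("seed", range(5))
    def test_and_monotonicity_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(
            {
                "diagnosis": rng.choice(["EP", "PSP"], 30),
                "a": rng.random(30),
                "b": rng.random(30),
            }
        )
        if frame["diagnosis"].nunique() < 2:
            return
        ra = CutoffRule("a", 0.5, "le")
        rb = CutoffRule("b", 0.5, "le")
        ma, mb = classify(frame, ra), classify(frame, rb)
        mab = combine_and(frame, [ra, rb])
        assert mab.specificity >= max(ma.specificity, mb.specificity) - 1e-12
        assert mab.sensitivity <= min(ma.sensitivity, mb.sensitivity) + 1e-12


class TestSurvival:
    def test_single_event_median(self):
        assert km_median([7.0], [True]) == 7.0

    def test_censoring_shifts_median(self):
        # all events at 5 except one censored at 4: median stays 5
        assert km_median([4, 5, 5, 5], [False, True, True, True]) == 5.0

    def test_log_rank_separated_groups(self):
        p = log_rank([1, 2, 3, 4], [1, 1, 1, 1], [10, 11, 12, 13], [1, 1, 1, 1])
        assert p < 0.01

    def test_fixture_pfs_log_rank_significant(self, cohort_df):
        tp, ep_ = survival_arrays(cohort_df, "PSP"), survival_arrays(cohort_df, "EP")
        assert log_rank(tp[0], tp[1], ep_[0], ep_[1]) < 0.001
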