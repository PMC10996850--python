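"""2x2 diagnostics: accuracy profile, AUC, chi-square, t and U tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from rmdv.diagnostics import (
    CE,
    HT,
    ContingencyTable2x2,
    binary_auc,
    build_table,
    diagnostic_summary,
    mann_whitney,
    pearson_chi2,
    welch_t,
)
from rmdv.errors import DegenerateTableError, InputError

from .oracles import chi2_observed_expected

STUDY_TABLE = ContingencyTable2x2(52, 6, 11, 34)

counts = st.integers(min_value=0, max_value=200)
pos_counts = st.integers(min_value=1, max_value=200)


class TestBuildTable:
    def test_study_labels_cross_tabulate(self):
        preds = [HT] * 52 + [CE] * 6 + [HT] * 11 + [CE] * 34
        outcs = [HT] * 58 + [CE] * 45
        t = build_table(preds, outcs)
        assert (t.a, t.b, t.c, t.d) == (52, 6, 11, 34)

    def test_all_correct(self):
        t = build_table([HT] * 3 + [CE] * 3, [HT] * 3 + [CE] * 3)
        assert (t.a, t.b, t.c, t.d) == (3, 0, 0, 3)

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            build_table([], [])

    def test_mismatched_ids_rejected(self):
        with pytest.raises(InputError):
            build_table({"p1": HT}, {"p2": HT})

    def test_dict_alignment_by_id(self):
        t = build_table({"b": CE, "a": HT}, {"a": HT, "b": CE})
        assert (t.a, t.b, t.c, t.d) == (1, 0, 0, 1)


class TestSummary:
    def test_study_profile(self):
        rep = diagnostic_summary(STUDY_TABLE)
        assert rep.sensitivity == pytest.approx(52 / 58)
        assert rep.specificity == pytest.approx(34 / 45)
        assert rep.ppv == pytest.approx(52 / 63)
        assert rep.npv == pytest.approx(34 / 40)
        assert rep.youden == pytest.approx(rep.sensitivity + rep.specificity - 1)

    def test_perfect_classifier(self):
        rep = diagnostic_summary(ContingencyTable2x2(1, 0, 0, 1))
        assert (rep.sensitivity, rep.specificity, rep.ppv, rep.npv) == (1, 1, 1, 1)
        assert rep.youden == 1.0
        assert rep.auc == 1.0

    def test_chance_classifier(self):
        rep = diagnostic_summary(ContingencyTable2x2(10, 10, 10, 10))
        assert (rep.sensitivity, rep.specificity, rep.ppv, rep.npv) == (
            0.5, 0.5, 0.5, 0.5)
        assert rep.youden == 0.0
        assert rep.auc == 0.5

    def test_degenerate_margin_names_quantity(self):
        with pytest.raises(DegenerateTableError, match="sensitivity"):
            diagnostic_summary(ContingencyTable2x2(0, 0, 5, 5))
        with pytest.raises(DegenerateTableError, match="PPV"):
            diagnostic_summary(ContingencyTable2x2(0, 5, 0, 5))


class TestAuc:
    @settings(deadline=None, derandomize=True)
    @given(a=pos_counts, b=counts, c=counts, d=pos_counts)
    def test_auc_equals_mean_of_se_sp(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        auc, _ = binary_auc(t)
        se = a / (a + b)
        sp = d / (c + d)
        assert auc == (se + sp) / 2

    def test_ci_brackets_auc(self):
        auc, (lo, hi) = binary_auc(STUDY_TABLE)
        assert lo <= auc <= hi
        assert 0 <= lo and hi <= 1


class TestChi2:
    def test_yates_correction_shrinks_statistic(self):
        plain, _ = pearson_chi2(STUDY_TABLE, correction=False)
        corrected, _ = pearson_chi2(STUDY_TABLE, correction=True)
        assert corrected < plain

    def test_independence_gives_zero(self):
        chi2, p = pearson_chi2(ContingencyTable2x2(5, 5, 5, 5))
        assert chi2 == 0.0
        assert p == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2(ContingencyTable2x2(0, 0, 5, 5))

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(a=counts, b=counts, c=counts, d=counts)
    def test_closed_form_matches_observed_expected_oracle(self, a, b, c, d):
        t = ContingencyTable2x2(a, b, c, d)
        if min(t.n_ht, t.n_ce, t.n_pos, t.n_neg) == 0:
            return
        chi2, _ = pearson_chi2(t)
        assert chi2 == pytest.approx(chi2_observed_expected(a, b, c, d), abs=1e-9)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(a=pos_counts, b=pos_counts, c=pos_counts, d=pos_counts)
    def test_symmetry_invariances(self, a, b, c, d):
        base, _ = pearson_chi2(ContingencyTable2x2(a, b, c, d))
        for t in (
            ContingencyTable2x2(c, d, a, b),  # swap rows
            ContingencyTable2x2(b, a, d, c),  # swap columns
            ContingencyTable2x2(a, c, b, d),  # transpose
        ):
            assert pearson_chi2(t)[0] == pytest.approx(base, rel=1e-12)

    def test_agrees_with_scipy_uncorrected(self):
        obs = np.array([[52, 6], [11, 34]])
        ref = stats.chi2_contingency(obs, correction=False)
        chi2, p = pearson_chi2(STUDY_TABLE)
        assert chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_monte_carlo_calibration_under_independence(self):
        """With both margins fixed, the uncorrected test rejects at ~5%."""
        rng = np.random.default_rng(2024)
        n, n_ht, n_pos = 103, 58, 63
        a = rng.hypergeometric(n_ht, n - n_ht, n_pos, size=10_000)
        b = n_ht - a
        c = n_pos - a
        d = (n - n_ht) - c
        num = (a * d - b * c).astype(float)
        chi2 = n * num**2 / (n_ht * (n - n_ht) * n_pos * (n - n_pos))
        reject = stats.chi2.sf(chi2, df=1) < 0.05
        assert 0.03 <= reject.mean() <= 0.08


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_study_age_row_from_summaries(self):
        t, p = welch_t((70.72, 9.19, 58), (66.56, 13.74, 45))
        assert t == pytest.approx(-1.75, abs=0.01)
        assert 0.05 < p < 0.15

    def test_large_shift_separates(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 50)
        t, p = welch_t(a, a + 10)
        assert p < 0.001

    def test_tiny_group_rejected(self):
        with pytest.raises(InputError):
            welch_t([1.0], [1.0, 2.0])


class TestMannWhitney:
    def test_complete_tie_singletons(self):
        u, z, p = mann_whitney([1], [1])
        assert u == 0.5
        assert z == 0.0

    def test_fully_separated_small_groups(self):
        u, z, p = mann_whitney([1, 2, 3], [4, 5, 6])
        assert u == 0.0  # min of the two U conventions
        assert z < 0
        assert p == pytest.approx(0.1)  # exact two-sided 2/20

    def test_large_shift_significant(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 60)
        u, z, p = mann_whitney(a, a + 2)
        assert p < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            mann_whitney([], [1.0])
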