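"""Response classification, ROC, prevalence ratios, exact tests, agreement."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from dyssync.errors import InvalidInputError, UndefinedROCError
from dyssync.phantom import CohortParams, simulate_cohort
from dyssync.stats import (
    bland_altman,
    classify_clinical,
    classify_rr,
    fisher_exact,
    phase2_model,
    prevalence_ratio,
    roc_analysis,
)


class TestClassification:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(200.0, 170.0, True), (175.0, 155.0, False), (150.0, 160.0, False)],
    )
    def test_reverse_remodelling_rule(self, pre, post, expected):
        assert classify_rr(pre, post) is expected

    def test_nonpositive_volume_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_rr(0.0, 100.0)

    @pytest.mark.parametrize(
        "walk,nyha,qol,expected",
        [
            (12.0, -1, -5.0, True),   # 2 of 3
            (5.0, 0, -25.0, False),   # 1 of 3
            (10.0, -1, -20.0, True),  # all boundaries inclusive
            (9.9, 0, -19.9, False),
        ],
    )
    def test_clinical_two_of_three_rule(self, walk, nyha, qol, expected):
        assert classify_clinical(walk, nyha, qol) is expected

    def test_classification_is_permutation_equivariant(self):
        rng = np.random.default_rng(0)
        pre = rng.uniform(100, 300, 50)
        post = rng.uniform(80, 300, 50)
        perm = rng.permutation(50)
        assert np.array_equal(classify_rr(pre, post)[perm], classify_rr(pre[perm], post[perm]))


def _mann_whitney_auc(scores, labels):
    """Brute-force pairwise AUC: P(score+ > score-) + 0.5 P(tie)."""
    pos = scores[labels]
    neg = scores[~labels]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        scores = np.r_[np.arange(10) + 10.0, np.arange(10)]
        labels = np.r_[np.ones(10), np.zeros(10)].astype(bool)
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(1.0)
        assert res.sens_at_cutoff == 1.0 and res.spec_at_cutoff == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_auc_equals_mann_whitney(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(20, 80)
        scores = np.round(rng.normal(size=n), 1)  # ties included
        labels = rng.random(n) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        res = roc_analysis(scores, labels)
        assert res.auc == pytest.approx(_mann_whitney_auc(scores, labels), abs=1e-12)

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(42)
        n1 = n0 = 500
        scores = rng.normal(size=n1 + n0)
        labels = np.r_[np.ones(n1), np.zeros(n0)].astype(bool)
        auc = roc_analysis(scores, labels).auc
        null_sd = np.sqrt((n1 + n0 + 1) / (12.0 * n1 * n0))
        assert abs(auc - 0.5) < 3 * null_sd

    def test_cutoff_reproduces_operating_point(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, 60) + np.r_[np.full(30, 1.2), np.zeros(30)]
        labels = np.r_[np.ones(30), np.zeros(30)].astype(bool)
        res = roc_analysis(scores, labels)
        pred = scores > res.optimal_cutoff
        assert res.sens_at_cutoff == pytest.approx(np.mean(pred[labels]))
        assert res.spec_at_cutoff == pytest.approx(np.mean(~pred[~labels]))

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedROCError):
            roc_analysis([1.0, 2.0], [True, True])


def _table_to_vectors(table):
    (a, b), (c, d) = table
    y = np.r_[np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)]
    x = np.r_[np.ones(a + b), np.zeros(c + d)]
    return y, x


class TestPrevalenceRatio:
    def test_printed_contingency_table_crude_ratio(self):
        """Exposed 27/29 vs unexposed 8/21 -> PR = 2.444."""
        y, x = _table_to_vectors([[27, 2], [8, 13]])
        res = prevalence_ratio(y, x)
        assert res.pr == pytest.approx((27 / 29) / (8 / 21), rel=1e-6)
        assert res.ci_low <= res.pr <= res.ci_high

    @pytest.mark.parametrize("seed", range(20))
    def test_single_binary_covariate_equals_crude_ratio(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 30, size=(2, 2))
        y, x = _table_to_vectors(table)
        res = prevalence_ratio(y, x)
        crude = (table[0, 0] / table[0].sum()) / (table[1, 0] / table[1].sum())
        assert res.pr == pytest.approx(crude, rel=1e-6)

    def test_null_association_covers_unity(self):
        rng = np.random.default_rng(5)
        n = 5000
        x = rng.random(n) < 0.5
        y = (rng.random(n) < 0.4).astype(float)
        res = prevalence_ratio(y, x.astype(float))
        assert res.ci_low < 1.0 < res.ci_high
        assert res.pr == pytest.approx(1.0, abs=0.1)

    def test_rank_deficient_design_rejected(self):
        y = np.array([1.0, 0, 1, 0])
        x = np.array([1.0, 1, 0, 0])
        with pytest.raises(InvalidInputError):
            prevalence_ratio(y, x, covariates=pd.DataFrame({"dup": x}))

    def test_nonbinary_outcome_rejected(self):
        with pytest.raises(InvalidInputError):
            prevalence_ratio(np.array([0.0, 1.0, 2.0]), np.array([0.0, 1.0, 0.0]))


def _fisher_enumeration(table):
    """Two-sided p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = np.asarray(table)
    n1, n2, m1 = a + b, c + d, a + c
    support = np.arange(max(0, m1 - n2), min(n1, m1) + 1)
    pmf = scipy.stats.hypergeom.pmf(support, n1 + n2, m1, n1)
    p_obs = scipy.stats.hypergeom.pmf(a, n1 + n2, m1, n1)
    return float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())


class TestFisherExact:
    def test_balanced_table_is_uninformative(self):
        assert fisher_exact([[5, 5], [5, 5]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("table", [[[27, 2], [8, 13]], [[1, 34], [7, 8]]])
    def test_printed_tables_are_highly_significant(self, table):
        p = fisher_exact(table)
        assert p < 0.001
        assert p == pytest.approx(_fisher_enumeration(table), rel=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidInputError):
            fisher_exact([[1, -2], [3, 4]])


class TestFisherSymmetries:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(st.lists(st.integers(0, 25), min_size=4, max_size=4))
    @settings(deadline=None, derandomize=True, max_examples=200)
    def test_invariant_under_transpose_and_row_swap(self, counts):
        a, b, c, d = counts
        p = fisher_exact([[a, b], [c, d]])
        assert fisher_exact([[a, c], [b, d]]) == pytest.approx(p, rel=1e-9)
        assert fisher_exact([[c, d], [a, b]]) == pytest.approx(p, rel=1e-9)
        assert 0.0 <= p <= 1.0 + 1e-12


class TestBlandAltman:
    def test_identical_series(self):
        res = bland_altman([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.mean_difference == 0.0 and res.cov_mean_pct == 0.0

    def test_constant_offset(self):
        a = np.array([10.0, 12.0, 15.0])
        res = bland_altman(a + 1.0, a)
        assert res.mean_difference == pytest.approx(1.0)
        assert res.sd_differences == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_cov_closed_form(self):
        """Pair (10, 11): SD/mean = 0.7071/10.5 -> 6.73%."""
        res = bland_altman([10.0, 20.0], [11.0, 20.0])
        covs = [np.std([10, 11], ddof=1) / 10.5 * 100, 0.0]
        assert res.cov_mean_pct == pytest.approx(np.mean(covs), abs=1e-6)


class TestPhase2Model:
    def test_dichotomization_cutoffs(self):
        df = pd.DataFrame(
            {
                "sdi": [9.75, 9.76, 20.0, 5.0],
                "qrs_ms": [149.9, 150.0, 180.0, 120.0],
                "qrs_morphology": ["LBBB", "RBBB", "IVCD", "LBBB"],
                "scar_burden": [14.7, 14.8, 0.0, 30.0],
                "rr": [0, 1, 1, 0],
            }
        )
        from dyssync.stats import _exposures

        e = _exposures(df)
        assert e["sdi_gt_9.75"].tolist() == [0.0, 1.0, 1.0, 0.0]  # strict >
        assert e["qrs_ge_150"].tolist() == [0.0, 1.0, 1.0, 0.0]  # inclusive >=
        assert e["lbbb"].tolist() == [1.0, 0.0, 0.0, 1.0]
        assert e["scar_gt_14.7"].tolist() == [0.0, 1.0, 0.0, 1.0]  # strict >

    def test_sdi_driven_cohort_identifies_only_sdi(self):
        """When only SDI drives outcome, its CI excludes 1 and the others don't."""
        cohort = simulate_cohort(CohortParams(n_patients=200, seed=4))
        models = phase2_model(cohort)
        sdi_uni = models["univariate"]["sdi_gt_9.75"]
        assert sdi_uni.ci_low > 1.0
        assert models["multivariate"]["sdi_gt_9.75"].ci_low > 1.0
        for name in ("qrs_ge_150", "lbbb", "scar_gt_14.7"):
            ci = models["multivariate"][name]
            assert ci.ci_low < 1.0 < ci.ci_high

    def test_null_cohort_covers_unity_everywhere(self):
        params = CohortParams(
            n_patients=400, p_rr_above_cutoff=0.55, p_rr_below_cutoff=0.55, seed=8
        )
        models = phase2_model(simulate_cohort(params))
        for res in models["univariate"].values():
            assert res.ci_low < 1.0 < res.ci_high
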