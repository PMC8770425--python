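"""Group statistics, multiple-testing control and outcome bookkeeping."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from dfcstates.stats import (
    ClinicalRecord,
    chi_square_2x2,
    classify_responder,
    conjunction_mask,
    fdr_bh,
    glm_group_test,
    paired_t,
    reduction_rate,
    two_sample_t_from_summary,
)


class TestGLM:
    def test_no_covariates_equals_pooled_t(self):
        rng = np.random.default_rng(0)
        y = np.concatenate([rng.normal(0.3, 1, 15), rng.normal(0, 1, 12)])
        g = np.concatenate([np.ones(15), np.zeros(12)])
        res = glm_group_test(y, g)
        t_ref, p_ref = sps.ttest_ind(y[g == 1], y[g == 0], equal_var=True)
        assert np.isclose(res.t_statistic, t_ref, atol=1e-10)
        assert np.isclose(res.p_value, p_ref, atol=1e-10)

    def test_matches_summary_based_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(1, 2, 20), rng.normal(0.5, 2, 25)
        res = glm_group_test(
            np.concatenate([a, b]),
            np.concatenate([np.ones(20), np.zeros(25)]),
        )
        t_sum, _ = two_sample_t_from_summary(
            a.mean(), a.std(ddof=1), 20, b.mean(), b.std(ddof=1), 25
        )
        assert np.isclose(res.t_statistic, t_sum, atol=1e-10)

    def test_orthogonal_covariate_leaves_coefficient_unchanged(self):
        # an orthogonal covariate cannot change the fitted group effect;
        # the t statistic only rescales by the lost residual df
        rng = np.random.default_rng(2)
        n = 40
        g = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])
        y = g * 0.5 + rng.standard_normal(n)
        raw = rng.standard_normal(n)
        basis = np.column_stack([np.ones(n), g, y])
        q, _ = np.linalg.qr(basis)
        cov = raw - q @ (q.T @ raw)
        res0 = glm_group_test(y, g)
        res1 = glm_group_test(y, g, pd.DataFrame({"c": cov}))
        # same RSS, df drops from n-2 to n-3: t_1 = t_0 * sqrt((n-3)/(n-2))
        assert np.isclose(
            res1.t_statistic,
            res0.t_statistic * np.sqrt((n - 3) / (n - 2)),
            atol=1e-10,
        )

    def test_rank_deficient_design_errors(self):
        y = np.arange(10.0)
        g = np.concatenate([np.ones(5), np.zeros(5)])
        with pytest.raises(ValueError, match="rank"):
            glm_group_test(y, g, pd.DataFrame({"dup": g}))

    def test_missing_y_errors(self):
        g = np.array([1.0, 1, 0, 0])
        with pytest.raises(ValueError, match="missing"):
            glm_group_test(np.array([1.0, np.nan, 0, 0]), g)


class TestPairedT:
    def test_hand_computed(self):
        # differences (1, 2, 3): mean 2, sd 1, t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        pre = np.array([0.0, 0.0, 0.0])
        post = np.array([1.0, 2.0, 3.0])
        t, p = paired_t(pre, post)
        assert np.isclose(t, 2 * np.sqrt(3))

    def test_identical_errors(self):
        x = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            paired_t(x, x)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(3)
        pre, post = rng.standard_normal(10), rng.standard_normal(10)
        t1, _ = paired_t(pre, post)
        t2, _ = paired_t(post, pre)
        assert np.isclose(t1, -t2)


class TestSummaryT:
    def test_cohort_age_summaries(self):
        # printed group summaries: 26.93 +/- 9.14 (n=70) vs 29.42 +/- 12.55 (n=43)
        t, p = two_sample_t_from_summary(26.93, 9.14, 70, 29.42, 12.55, 43)
        assert round(t, 3) == -1.217
        assert round(p, 3) == 0.226

    def test_identical_summaries(self):
        t, _ = two_sample_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0

    def test_matches_raw_data_pooled_t(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a, b = rng.normal(0, 1, 12), rng.normal(0.4, 1.3, 17)
            t_sum, p_sum = two_sample_t_from_summary(
                a.mean(), a.std(ddof=1), 12, b.mean(), b.std(ddof=1), 17
            )
            t_raw, p_raw = sps.ttest_ind(a, b, equal_var=True)
            assert np.isclose(t_sum, t_raw, atol=1e-10)
            assert np.isclose(p_sum, p_raw, atol=1e-10)

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            two_sample_t_from_summary(1.0, 0.0, 5, 1.0, 0.0, 5)


class TestChiSquare:
    def test_cohort_sex_table(self):
        # 21/49 male/female patients vs 16/27 controls
        chi2, p = chi_square_2x2(np.array([[21, 49], [16, 27]]))
        assert round(chi2, 3) == 0.629
        assert round(p, 3) == 0.428

    def test_independence_gives_zero(self):
        chi2, _ = chi_square_2x2(np.array([[10, 10], [10, 10]]))
        assert np.isclose(chi2, 0.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            t = rng.integers(1, 60, size=(2, 2))
            chi2, _ = chi_square_2x2(t)
            exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
            assert np.isclose(chi2, ((t - exp) ** 2 / exp).sum(), atol=1e-10)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(np.array([[0, 0], [5, 7]]))


def bh_stepup_oracle(p, q):
    """Literal step-up definition: largest k with p_(k) <= k q / m."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_star = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestFDR:
    def test_all_small(self):
        q, rej = fdr_bh(np.full(10, 0.01))
        assert rej.all()
        assert np.allclose(q, 0.01)

    def test_stepup_by_hand(self):
        # thresholds k*0.05/4 = 0.0125, 0.025, 0.0375, 0.05;
        # p_(3) = 0.04 > 0.0375, so the step-up stops at k = 2
        p = np.array([0.01, 0.02, 0.04, 0.5])
        q, rej = fdr_bh(p)
        assert list(rej) == [True, True, False, False]
        assert np.array_equal(rej, bh_stepup_oracle(p, 0.05))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        p = rng.random(12)
        perm = rng.permutation(12)
        q1, r1 = fdr_bh(p)
        q2, r2 = fdr_bh(p[perm])
        assert np.allclose(q1[perm], q2)
        assert np.array_equal(r1[perm], r2)

    def test_matches_stepup_definition(self):
        rng = np.random.default_rng(7)
        for m in range(1, 11):
            for _ in range(20):
                p = rng.random(m)
                _, rej = fdr_bh(p, 0.05)
                assert np.array_equal(rej, bh_stepup_oracle(p, 0.05))

    def test_invalid_p_errors(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))


class TestConjunction:
    def test_alpha_one_includes_all(self):
        rng = np.random.default_rng(8)
        g1 = rng.standard_normal((10, 5, 5))
        g2 = rng.standard_normal((12, 5, 5))
        mask = conjunction_mask(g1, g2, alpha=1.0)
        off = ~np.eye(5, dtype=bool)
        assert mask[off].all()

    def test_null_edges_mostly_excluded(self):
        # many independent null edges stand in for repeated simulations
        rng = np.random.default_rng(9)
        g1 = rng.standard_normal((15, 30, 30))
        g2 = rng.standard_normal((15, 30, 30))
        g1 = (g1 + np.transpose(g1, (0, 2, 1))) / 2
        g2 = (g2 + np.transpose(g2, (0, 2, 1))) / 2
        mask = conjunction_mask(g1, g2, alpha=0.05)
        iu = np.triu_indices(30, 1)
        assert mask[iu].mean() < 0.2  # union of two 5% tests, expect ~10%
        mask_i = conjunction_mask(g1, g2, alpha=0.05, combine="intersection")
        assert mask_i[iu].mean() < 0.02

    def test_planted_edge_included(self):
        rng = np.random.default_rng(10)
        g1 = rng.standard_normal((12, 6, 6)) * 0.2
        g2 = rng.standard_normal((12, 6, 6)) * 0.2
        g1[:, 0, 1] = g1[:, 1, 0] = 1.0 + 0.2 * rng.standard_normal(12)
        mask = conjunction_mask(g1, g2, alpha=0.05)
        assert mask[0, 1]

    def test_small_group_excluded_under_intersection(self):
        g1 = np.full((1, 4, 4), 0.5)  # single subject: no one-sample test
        g2 = np.tile(np.full((4, 4), 0.5), (10, 1, 1))
        mask = conjunction_mask(g1, g2, alpha=0.05, combine="intersection")
        assert not mask.any()


class TestOutcome:
    def test_exact_50_percent_is_nonresponder(self):
        rr = reduction_rate(28, 14)
        assert rr == 50.0
        assert classify_responder(rr) is False

    def test_week12_zero_full_response(self):
        rr = reduction_rate(20, 0)
        assert rr == 100.0
        assert classify_responder(rr) is True

    def test_cohort_responder_share(self):
        # 37 completers, 23 above the 50% reduction threshold
        rng = np.random.default_rng(11)
        records = []
        for i in range(37):
            base = int(rng.integers(20, 35))
            if i < 23:
                week12 = int(base * (1 - 0.6))  # ~60% reduction
            else:
                week12 = int(np.ceil(base * 0.6))  # ~40% reduction
            records.append(
                ClinicalRecord(f"s{i}", "MDD", 30.0, "F", 0.1, base, week12)
            )
        share = 100 * np.mean([r.responder for r in records])
        assert round(share, 2) == 62.16

    def test_missing_week12_gives_missing_outcome(self):
        r = ClinicalRecord("s", "MDD", 30.0, "M", 0.1, 28)
        assert r.rr is None and r.responder is None

    def test_invalid_baseline_errors(self):
        with pytest.raises(ValueError):
            reduction_rate(0, 0)
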