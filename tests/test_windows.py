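"""Sliding-window estimation: taper, weighted covariance, graphical LASSO."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dfcstates.windows import (
    GlassoError,
    SubjectTimeSeries,
    compute_windowed_fc,
    count_windows,
    cov_to_fisher_z,
    glasso_fit,
    glasso_objective,
    make_taper,
    select_lambda,
    weighted_window_cov,
    _window_correlations,
)


class TestCountWindows:
    def test_default_study_geometry(self):
        # 240 volumes minus 10 discarded, 22-TR window, 1-TR step
        assert count_windows(230, 22, 1) == 209

    def test_single_full_window(self):
        assert count_windows(22, 22, 1) == 1

    def test_strided(self):
        # brute force: starts 0,5,10,15,20 fit in T=30 with L=10
        assert count_windows(30, 10, 5) == 5

    def test_too_short_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            count_windows(10, 22, 1)

    @given(
        t=st.integers(1, 400), length=st.integers(1, 60), step=st.integers(1, 10)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration(self, t, length, step):
        if t < length:
            with pytest.raises(ValueError):
                count_windows(t, length, step)
            return
        starts = [s for s in range(0, t) if s % step == 0 and s + length <= t]
        assert count_windows(t, length, step) == len(starts)


def taper_oracle(length, sigma):
    """Direct-summation convolution of a rectangle with a discrete Gaussian."""
    half = int(np.ceil(3 * sigma))
    t = np.arange(-half, half + 1)
    g = np.exp(-0.5 * (t / sigma) ** 2)
    g = g / g.sum()
    full = np.zeros(length + 2 * half)
    for i in range(length):  # rectangle taps
        for j, gv in enumerate(g):
            full[i + j] += gv
    w = full[half : half + length]
    return w / w.sum()


class TestTaper:
    def test_sigma_zero_uniform(self):
        t = make_taper(22, 0.0)
        assert np.allclose(t.weights, 1.0 / 22)

    def test_matches_convolution_oracle(self):
        t = make_taper(22, 3.0)
        assert np.allclose(t.weights, taper_oracle(22, 3.0), atol=1e-12)

    @pytest.mark.parametrize("length,sigma", [(22, 3.0), (10, 1.5), (5, 4.0)])
    def test_symmetric_unit_sum(self, length, sigma):
        t = make_taper(length, sigma)
        assert np.allclose(t.weights, t.weights[::-1])
        assert np.isclose(t.weights.sum(), 1.0)
        assert np.all(t.weights > 0)


class TestWeightedCov:
    def test_uniform_equals_population_cov(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((40, 5))
        s = weighted_window_cov(x, make_taper(40, 0.0))
        assert np.allclose(s, np.cov(x.T, bias=True), atol=1e-12)

    def test_two_point_hand_computation(self):
        # weights (1/2, 1/2), x = [[0, 0], [2, 4]]: mu = (1, 2),
        # S = 0.5[(-1,-2)'(-1,-2) + (1,2)'(1,2)] = [[1, 2], [2, 4]]
        x = np.array([[0.0, 0.0], [2.0, 4.0]])
        s = weighted_window_cov(x, make_taper(2, 0.0))
        assert np.allclose(s, [[1.0, 2.0], [2.0, 4.0]])

    def test_positive_semidefinite(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            x = rng.standard_normal((22, 8))
            s = weighted_window_cov(x, make_taper(22, 3.0))
            assert np.linalg.eigvalsh(s).min() >= -1e-10


class TestGlasso:
    def test_lambda_zero_returns_input(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((300, 6))
        s = np.cov(x.T)
        cov, prec = glasso_fit(s, 0.0)
        assert np.abs(cov - s).max() < 1e-6
        assert np.allclose(prec @ s, np.eye(6), atol=1e-8)

    @pytest.mark.parametrize("s12,lam", [(0.6, 0.2), (0.6, 0.7), (-0.5, 0.2), (0.3, 0.05)])
    def test_2x2_closed_form(self, s12, lam):
        s = np.array([[1.0, s12], [s12, 1.0]])
        cov, _ = glasso_fit(s, lam, tol=1e-10)
        expected = np.sign(s12) * max(abs(s12) - lam, 0.0)
        assert abs(cov[0, 1] - expected) < 1e-8

    def test_agrees_with_independent_solver(self):
        from sklearn.covariance import graphical_lasso as skl_glasso

        rng = np.random.default_rng(3)
        x = rng.standard_normal((150, 10))
        s = np.corrcoef(x.T)
        cov, prec = glasso_fit(s, 0.1, tol=1e-8)
        cov2, prec2 = skl_glasso(s, alpha=0.1, tol=1e-10, max_iter=500)
        assert np.abs(cov - cov2).max() < 5e-3
        assert np.abs(prec - prec2).max() < 5e-3

    def test_full_shrinkage_diagonal_precision(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((100, 5))
        s = np.corrcoef(x.T)
        _, prec = glasso_fit(s, 2.0 * np.abs(s - np.eye(5)).max())
        off = prec[~np.eye(5, dtype=bool)]
        assert np.abs(off).max() < 1e-10

    def test_objective_monotone_nonincreasing(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((30, 12))
        s = np.corrcoef(x.T)
        out = glasso_fit(s, 0.05, track_objective=True)
        objs = out[-1]
        assert all(b <= a + 1e-9 for a, b in zip(objs, objs[1:]))

    def test_duality_gap_below_tolerance(self):
        from dfcstates.windows import _dual_gap

        rng = np.random.default_rng(6)
        x = rng.standard_normal((25, 10))
        s = np.corrcoef(x.T)
        _, prec = glasso_fit(s, 0.08, tol=1e-4)
        assert abs(_dual_gap(s, prec, 0.08)) <= 1e-4

    def test_nonconvergence_carries_gap(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((25, 15))
        s = np.corrcoef(x.T)
        with pytest.raises(GlassoError) as err:
            glasso_fit(s, 0.02, tol=1e-12, max_iter=1)
        assert err.value.gap is not None

    def test_warm_start_matches_cold(self):
        # covariance entries at zero-precision coordinates are determined
        # only to within the penalty band at finite tolerance, so warm and
        # cold solves agree to ~1e-2 on rank-deficient inputs
        rng = np.random.default_rng(8)
        x1 = rng.standard_normal((22, 9))
        x2 = x1 + 0.1 * rng.standard_normal((22, 9))
        s1, s2 = np.corrcoef(x1.T), np.corrcoef(x2.T)
        _, _, state = glasso_fit(s1, 0.1, return_state=True)
        cov_warm, _, _ = glasso_fit(s2, 0.1, tol=1e-6, warm_start=state, return_state=True)
        cov_cold, _ = glasso_fit(s2, 0.1, tol=1e-6)
        assert np.abs(cov_warm - cov_cold).max() < 1e-2


class TestFisherZ:
    def test_identity_gives_zero(self):
        assert np.allclose(cov_to_fisher_z(np.eye(4)), 0.0)

    def test_half_correlation(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        z = cov_to_fisher_z(cov)
        assert np.isclose(z[0, 1], np.arctanh(0.5))

    def test_clipping_keeps_finite(self):
        cov = np.array([[1.0, 1.0], [1.0, 1.0]])
        z = cov_to_fisher_z(cov)
        assert np.isfinite(z).all()
        assert np.isclose(z[0, 1], np.arctanh(1 - 1e-7))

    def test_nonpositive_diagonal_errors(self):
        with pytest.raises(ValueError, match="diagonal"):
            cov_to_fisher_z(np.array([[0.0, 0.1], [0.1, 1.0]]))

    def test_sign_flip_antisymmetry(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal((200, 4))
        s = np.cov(x.T)
        z = cov_to_fisher_z(s)
        flip = np.diag([1.0, -1.0, 1.0, 1.0])
        z_flipped = cov_to_fisher_z(flip @ s @ flip)
        expected = z.copy()
        expected[1, :] *= -1
        expected[:, 1] *= -1
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(z_flipped, expected, atol=1e-12)

    @given(st.floats(-5, 5))
    @settings(max_examples=50, deadline=None)
    def test_atanh_tanh_roundtrip(self, z):
        assert abs(np.arctanh(np.tanh(z)) - z) < 1e-12


def _chain_window_corrs(n_roi, length, n_win, seed):
    """Windows drawn from a known sparse-precision (chain graph) model."""
    theta = np.eye(n_roi)
    for i in range(n_roi - 1):
        theta[i, i + 1] = theta[i + 1, i] = -0.45
    cov = np.linalg.inv(theta)
    d = np.sqrt(np.diag(cov))
    chol = np.linalg.cholesky(cov / np.outer(d, d))
    rng = np.random.default_rng(seed)
    taper = make_taper(length, 0.0)
    out = []
    for _ in range(n_win):
        x = rng.standard_normal((length, n_roi)) @ chol.T
        s = weighted_window_cov(x, taper)
        dg = np.diag(s)
        out.append(s / np.sqrt(np.outer(dg, dg)))
    return np.array(out)


class TestSelectLambda:
    def test_single_candidate(self):
        corrs = _chain_window_corrs(6, 30, 6, 0)
        assert select_lambda(corrs, grid=np.array([0.3]), folds=5, reps=2, seed=0) == 0.3

    def test_interior_optimum_on_sparse_precision_data(self):
        corrs = _chain_window_corrs(12, 14, 15, 3)
        grid = np.logspace(-2, 0, 8)
        lam = select_lambda(corrs, grid=grid, folds=5, reps=5, seed=0)
        assert grid[0] < lam < grid[-1]

    def test_selected_beats_endpoints_on_heldout_likelihood(self):
        from dfcstates.windows import _heldout_loglik

        corrs = _chain_window_corrs(12, 14, 15, 3)
        grid = np.logspace(-2, 0, 8)
        lam = select_lambda(corrs, grid=grid, folds=5, reps=5, seed=0)
        fit_idx, held_idx = np.arange(8), np.arange(8, 15)

        def score(lv):
            _, theta = glasso_fit(corrs[0], lv, tol=1e-6, max_iter=500)
            return np.mean([_heldout_loglik(theta, corrs[h]) for h in held_idx])

        assert score(lam) >= score(grid[0])
        assert score(lam) >= score(grid[-1])

    def test_deterministic(self):
        corrs = _chain_window_corrs(8, 20, 12, 1)
        grid = np.logspace(-2, 0, 5)
        a = select_lambda(corrs, grid=grid, folds=4, reps=3, seed=9)
        b = select_lambda(corrs, grid=grid, folds=4, reps=3, seed=9)
        assert a == b

    def test_degenerate_grid_errors(self):
        corrs = _chain_window_corrs(6, 30, 6, 0)
        with pytest.raises(ValueError):
            select_lambda(corrs, grid=np.array([np.inf]), folds=3, reps=1, seed=0)


class TestComputeWindowedFC:
    def test_window_count_209(self, cohort, baseline_windowed):
        wfc = next(iter(baseline_windowed.values()))
        assert wfc.n_windows == 209
        assert wfc.n_rois == 36
        assert np.allclose(wfc.z_fc, np.transpose(wfc.z_fc, (0, 2, 1)))
        assert np.allclose(wfc.z_fc[:, np.arange(36), np.arange(36)], 0.0)

    def test_stationary_series_mean_matches_static(self):
        # long stationary Gaussian: across-window mean z-FC tracks static z-FC
        rng = np.random.default_rng(12)
        c = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.3], [0.2, 0.3, 1.0]])
        x = rng.standard_normal((1200, 3)) @ np.linalg.cholesky(c).T
        ts = SubjectTimeSeries("s", "HC", "baseline", x)
        wfc = compute_windowed_fc(ts, make_taper(22, 3.0), step=10, lam=0.01)
        mean_z = wfc.z_fc.mean(axis=0)
        static_z = np.arctanh(np.clip(np.corrcoef(x.T), -0.999, 0.999))
        np.fill_diagonal(static_z, 0.0)
        assert np.abs(mean_z - static_z).max() < 0.1

    def test_constant_channel_errors(self):
        x = np.random.default_rng(13).standard_normal((60, 3))
        x[:, 1] = 2.0
        ts = SubjectTimeSeries("s", "HC", "baseline", x)
        with pytest.raises(ValueError, match="zero-variance"):
            compute_windowed_fc(ts, make_taper(22, 3.0), lam=0.1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(14)
        x = rng.standard_normal((80, 5))
        ts = SubjectTimeSeries("s", "HC", "baseline", x)
        grid = np.logspace(-1.5, 0, 4)
        a = compute_windowed_fc(ts, make_taper(22, 3.0), lam=None, grid=grid, reps=2, seed=7)
        b = compute_windowed_fc(ts, make_taper(22, 3.0), lam=None, grid=grid, reps=2, seed=7)
        assert a.lambda_selected == b.lambda_selected
        assert np.array_equal(a.z_fc, b.z_fc)


def test_glasso_objective_finite_at_solution():
    rng = np.random.default_rng(15)
    s = np.corrcoef(rng.standard_normal((50, 6)).T)
    _, prec = glasso_fit(s, 0.1)
    assert np.isfinite(glasso_objective(s, prec, 0.1))
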