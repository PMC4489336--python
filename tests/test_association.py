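import numpy as np
import pytest
from scipy import stats

from wgsig.association import (
    DegenerateTestError,
    WeightScheme,
    beta_weights,
    burden_test,
    fit_null_model,
    flat_weights,
    quad_form_pvalue,
    quad_form_pvalue_info,
    single_marker_test,
    skat_test,
    skato_test,
)


@pytest.fixture()
def toy_window(rng):
    n, k = 40, 5
    g = rng.binomial(2, 0.1, size=(n, k)).astype(float)
    while np.any(g.std(axis=0) == 0):
        g = rng.binomial(2, 0.1, size=(n, k)).astype(float)
    y = rng.standard_normal(n)
    return g, y


class TestNullModel:
    def test_residuals_sum_to_zero(self, rng):
        nm = fit_null_model(rng.standard_normal(50))
        assert abs(nm.residuals.sum()) < 1e-10

    def test_projection_idempotent(self, rng):
        y = rng.standard_normal(30)
        x = rng.standard_normal((30, 2))
        nm = fit_null_model(y, covariates=x)
        v = rng.standard_normal(30)
        np.testing.assert_allclose(nm.project(nm.project(v)), nm.project(v), atol=1e-12)

    def test_sigma2(self, rng):
        y = rng.standard_normal(100)
        nm = fit_null_model(y)
        assert nm.sigma2 == pytest.approx(y.var(ddof=1))


class TestSingleMarker:
    def test_perfect_fit_floors_p(self):
        x = np.array([0, 0, 1, 1, 2, 2], dtype=float)
        y = 3.0 * (x - x.mean()) + 1.0
        nm = fit_null_model(y)
        p = single_marker_test(x, nm)
        assert 0 < p <= 1e-300

    def test_orthogonal_gives_p_one(self):
        x = np.array([0.0, 1.0, 2.0, 1.0])
        xc = x - x.mean()
        y = np.array([1.0, -1.0, 1.0, -1.0])
        y -= (y @ xc) / (xc @ xc) * xc  # force exact orthogonality
        nm = fit_null_model(y)
        assert single_marker_test(x, nm) == pytest.approx(1.0)

    def test_f_equals_t_squared(self):
        x = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        y = np.array([0.3, 1.1, 1.9, -0.2, 0.8, 2.5])
        res = stats.linregress(x, y)
        nm = fit_null_model(y)
        p = single_marker_test(x, nm)
        assert p == pytest.approx(res.pvalue, rel=1e-9)
        # F = t^2 identity via the P-value correspondence F(1, n-2) = t(n-2)^2
        f_stat = res.rvalue**2 / (1 - res.rvalue**2) * 4
        assert stats.f.sf(f_stat, 1, 4) == pytest.approx(p, rel=1e-9)

    def test_constant_dosage_raises(self):
        nm = fit_null_model(np.arange(6, dtype=float))
        with pytest.raises(DegenerateTestError):
            single_marker_test(np.ones(6), nm)


class TestBurden:
    def test_single_variant_window_equals_single_marker(self, toy_window):
        g, y = toy_window
        nm = fit_null_model(y)
        res = burden_test(g[:, [0]], y, nm)
        assert res.p_value == pytest.approx(single_marker_test(g[:, 0], nm))

    def test_orthogonal_score_p_one(self):
        g = np.array([[0.0], [1.0], [2.0], [1.0]])
        x = g.sum(axis=1)
        xc = x - x.mean()
        y = np.array([1.0, -1.0, 1.0, -1.0])
        y -= (y @ xc) / (xc @ xc) * xc
        res = burden_test(g, y, fit_null_model(y))
        assert res.p_value == pytest.approx(1.0)

    def test_type_i_error_monte_carlo(self, small_cohort):
        from wgsig.store import _batch_f_pvalues

        g = small_cohort.dosages[:, :30]
        x = g.sum(axis=1, keepdims=True)
        rng = np.random.default_rng(5)
        y = rng.standard_normal((small_cohort.n_individuals, 2000))
        p = _batch_f_pvalues(x, y).ravel()
        rate = (p < 0.05).mean()
        tol = 2 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(rate - 0.05) < tol

    def test_constant_burden_raises(self, rng):
        g = np.ones((20, 3))
        y = rng.standard_normal(20)
        with pytest.raises(DegenerateTestError):
            burden_test(g, y, fit_null_model(y))


class TestQuadFormPValue:
    def test_single_chi_square(self):
        assert quad_form_pvalue([1.0], 3.841) == pytest.approx(0.05, abs=2e-4)

    def test_chi_square_three(self):
        assert quad_form_pvalue([1.0, 1.0, 1.0], 7.815) == pytest.approx(0.05, abs=2e-4)

    def test_against_monte_carlo(self, rng):
        lam = np.array([2.0, 1.0])
        n_draws = 10**6
        draws = 2.0 * rng.chisquare(1, n_draws) + rng.chisquare(1, n_draws)
        mc = (draws > 5.0).mean()
        se = np.sqrt(mc * (1 - mc) / n_draws)
        p, method = quad_form_pvalue_info(lam, 5.0)
        assert method == "imhof"
        assert abs(p - mc) < 3 * se

    def test_deep_tail_uses_liu(self):
        p, method = quad_form_pvalue_info([1.0, 0.5], 200.0)
        assert method == "liu"
        assert 0 < p < 1e-20

    def test_zero_statistic(self):
        assert quad_form_pvalue([1.0, 2.0], 0.0) == 1.0

    def test_all_zero_spectrum(self):
        with pytest.raises(DegenerateTestError):
            quad_form_pvalue([0.0, 0.0], 1.0)

    def test_tiny_eigenvalues_truncated(self):
        p_full = quad_form_pvalue([1.0, 1e-15], 3.841)
        assert p_full == pytest.approx(quad_form_pvalue([1.0], 3.841))


class TestSkat:
    def test_zero_residuals_give_p_one(self):
        y = np.full(10, 2.5)
        y[0] = 2.5  # constant: residuals identically zero
        g = np.zeros((10, 2))
        g[:3, 0] = 1
        g[5:7, 1] = 1
        nm = fit_null_model(np.concatenate([y]))
        res = skat_test(g, y, flat_weights(2), nm)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_brute_force_kernel_expansion(self, rng):
        g = np.array(
            [[0.0, 1.0], [1.0, 0.0], [2.0, 1.0], [0.0, 0.0]]
        )
        y = np.array([0.2, -0.4, 1.3, -0.8])
        nm = fit_null_model(y)
        w = np.array([1.0, 1.0])
        res = skat_test(g, y, WeightScheme("flat", w), nm)
        gc = g - g.mean(axis=0)
        k_mat = (gc * w) @ (gc * w).T
        e = y - y.mean()
        assert res.statistic == pytest.approx(float(e @ k_mat @ e), rel=1e-12)

    def test_type_i_error_monte_carlo(self, small_cohort):
        g = small_cohort.dosages[:, :25]
        weights = beta_weights(small_cohort.maf[:25])
        rng = np.random.default_rng(6)
        hits = 0
        n_rep = 2000
        ys = rng.standard_normal((small_cohort.n_individuals, n_rep))
        for r in range(n_rep):
            nm = fit_null_model(ys[:, r])
            if skat_test(g, ys[:, r], weights, nm).p_value < 0.05:
                hits += 1
        rate = hits / n_rep
        upper = 0.05 + 2 * np.sqrt(0.05 * 0.95 / n_rep)
        assert rate <= upper  # within binomial error, or conservative

    def test_zero_kernel_raises(self, rng):
        y = rng.standard_normal(12)
        with pytest.raises(DegenerateTestError):
            skat_test(np.ones((12, 2)), y, flat_weights(2), fit_null_model(y))


class TestSkatO:
    def test_rho_zero_reduces_to_skat(self, toy_window):
        g, y = toy_window
        nm = fit_null_model(y)
        w = flat_weights(g.shape[1])
        p_skat = skat_test(g, y, w, nm).p_value
        p_skato = skato_test(g, y, w, nm, rho_grid=[0.0]).p_value
        assert p_skato == pytest.approx(p_skat, rel=1e-6)

    def test_rho_one_reduces_to_weighted_burden_quadform(self, toy_window):
        g, y = toy_window
        nm = fit_null_model(y)
        w = flat_weights(g.shape[1])
        res = skato_test(g, y, w, nm, rho_grid=[1.0])
        # weighted burden kernel: rank-one quadratic form in the summed score
        gc = nm.project(g - g.mean(axis=0))
        z = gc.sum(axis=1)
        q = (float(z @ (nm.residuals / np.sqrt(nm.sigma2)))) ** 2
        lam = float(z @ z)
        expected = quad_form_pvalue([lam], q)
        assert res.p_value == pytest.approx(expected, rel=1e-6)

    def test_default_grid_bounds(self, toy_window):
        g, y = toy_window
        nm = fit_null_model(y)
        w = beta_weights(g.mean(axis=0) / 2)
        res = skato_test(g, y, w, nm)
        assert 0 < res.p_value <= 1
        # min-P combination lies between its best component and Bonferroni
        t_min = res.statistic
        assert t_min <= res.p_value <= min(8 * t_min, 1.0) + 1e-12

    def test_grid_validation(self, toy_window):
        g, y = toy_window
        nm = fit_null_model(y)
        w = flat_weights(g.shape[1])
        with pytest.raises(ValueError):
            skato_test(g, y, w, nm, rho_grid=[])
        with pytest.raises(ValueError):
            skato_test(g, y, w, nm, rho_grid=[0.5, 0.0])

    def test_type_i_error_small(self, small_cohort):
        g = small_cohort.dosages[:, 40:60]
        weights = beta_weights(small_cohort.maf[40:60])
        rng = np.random.default_rng(8)
        n_rep = 300
        hits = 0
        for r in range(n_rep):
            y = rng.standard_normal(small_cohort.n_individuals)
            nm = fit_null_model(y)
            if skato_test(g, y, weights, nm).p_value < 0.05:
                hits += 1
        upper = 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_rep)
        assert hits / n_rep <= upper


class TestInvariances:
    def test_constant_shift_of_y(self, toy_window):
        g, y = toy_window
        w = flat_weights(g.shape[1])
        r1 = skat_test(g, y, w, fit_null_model(y))
        r2 = skat_test(g, y + 100.0, w, fit_null_model(y + 100.0))
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-6)
        b1 = burden_test(g, y, fit_null_model(y))
        b2 = burden_test(g, y + 100.0, fit_null_model(y + 100.0))
        assert b1.p_value == pytest.approx(b2.p_value, rel=1e-9)

    def test_skat_invariant_to_variant_order(self, toy_window, rng):
        g, y = toy_window
        nm = fit_null_model(y)
        perm = rng.permutation(g.shape[1])
        r1 = skat_test(g, y, flat_weights(g.shape[1]), nm)
        r2 = skat_test(g[:, perm], y, flat_weights(g.shape[1]), nm)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-12)

    def test_burden_invariant_to_joint_individual_permutation(self, toy_window, rng):
        g, y = toy_window
        perm = rng.permutation(g.shape[0])
        r1 = burden_test(g, y, fit_null_model(y))
        r2 = burden_test(g[perm], y[perm], fit_null_model(y[perm]))
        assert r1.p_value == pytest.approx(r2.p_value, rel=1e-9)

    def test_single_variant_window_rank_agreement(self, small_cohort):
        # skat and burden on a 1-variant window are monotone transforms of
        # the same score: their P-value sequences agree in rank
        g = small_cohort.dosages[:, [3]]
        w = flat_weights(1)
        rng = np.random.default_rng(11)
        p_skat, p_burden = [], []
        for _ in range(60):
            y = rng.standard_normal(small_cohort.n_individuals)
            nm = fit_null_model(y)
            p_skat.append(skat_test(g, y, w, nm).p_value)
            p_burden.append(burden_test(g, y, nm).p_value)
        rho = stats.spearmanr(p_skat, p_burden).statistic
        assert rho > 0.999
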