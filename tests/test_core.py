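"""Covariance construction, REML likelihood and AI-REML fits against
independent symbolic and dense-matrix oracles."""

import numpy as np
import pytest
from scipy.linalg import null_space

import mrnm
from mrnm.core import (
    FULL_PARAMS,
    NULL_PARAMS,
    MRNMFit,
    MRNMParams,
    build_covariance,
    default_design,
    reml_loglik,
    variance_function,
    variance_proportions,
)
from mrnm.errors import NotPositiveDefiniteError, ParameterError
from _helpers import simulate_and_fit, standardize


def _random_params(rng, model="full"):
    """Random parameters with comfortably PD implied covariance."""
    a = rng.standard_normal((3, 3)) * 0.15
    sigma_g = a @ a.T + 0.05 * np.eye(3)
    b = rng.standard_normal((3, 3)) * 0.2
    sigma_e = b @ b.T + 0.4 * np.eye(3)
    full = MRNMParams.from_matrices(sigma_g, sigma_e)
    if model == "full":
        return full
    vals = [full[name] for name in NULL_PARAMS]
    return MRNMParams("null", np.array(vals))


class TestBuildCovariance:
    def test_two_individual_symbolic_expansion(self):
        # independent hand expansion of the four blocks at n = 2
        K = np.array([[1.0, 0.5], [0.5, 1.0]])
        c = np.array([1.0, -1.0])
        vals = np.full(12, 0.05)
        vals[[0, 2, 5, 6, 8, 11]] = 0.1  # diagonals 0.1, covariances 0.05
        p = MRNMParams("full", vals)
        V = build_covariance(p, K, c)

        s = dict(zip(FULL_PARAMS, vals))
        n = 2
        YY = np.zeros((2, 2))
        YC = np.zeros((2, 2))
        CC = np.zeros((2, 2))
        for i in range(n):
            for j in range(n):
                YY[i, j] = (
                    s["var_a0"] * K[i, j]
                    + s["cov_a0a1"] * (K[i, j] * c[j] + c[i] * K[i, j])
                    + s["var_a1"] * c[i] * K[i, j] * c[j]
                    + (s["var_t0"] + 2 * s["cov_t0t1"] * c[i]
                       + s["var_t1"] * c[i] ** 2) * (i == j)
                )
                YC[i, j] = (
                    s["cov_a0b0"] * K[i, j]
                    + s["cov_a1b0"] * c[i] * K[i, j]
                    + (s["cov_t0e0"] + s["cov_t1e0"] * c[i]) * (i == j)
                )
                CC[i, j] = s["var_b0"] * K[i, j] + s["var_e0"] * (i == j)
        expected = np.block([[YY, YC], [YC.T, CC]])
        np.testing.assert_allclose(V, expected, atol=1e-14)

    def test_zero_interactions_reduce_to_bivariate_greml(self):
        rng = np.random.default_rng(0)
        K = np.eye(4) + 0.1
        c = standardize(rng.standard_normal(4))
        full_vals = np.zeros(12)
        full_vals[[0, 3, 5, 6, 9, 11]] = [0.3, 0.1, 0.4, 0.7, 0.05, 0.6]
        V_full = build_covariance(MRNMParams("full", full_vals), K, c)
        null_vals = np.array([0.3, 0.1, 0.4, 0.7, 0.05, 0.6])
        V_null = build_covariance(MRNMParams("null", null_vals), K, c)
        np.testing.assert_allclose(V_full, V_null, atol=1e-14)
        # and the YY block is exactly var_a0*K + var_t0*I
        np.testing.assert_allclose(
            V_full[:4, :4], 0.3 * K + 0.7 * np.eye(4), atol=1e-14
        )

    def test_zero_gradient_kills_all_slope_terms(self):
        rng = np.random.default_rng(1)
        K = np.eye(5)
        c = np.zeros(5)
        p = _random_params(rng, "full")
        V = build_covariance(p, K, c)
        stripped = p.values.copy()
        stripped[[1, 2, 4, 7, 8, 10]] = 0.0  # every alpha1/tau1 entry
        V0 = build_covariance(MRNMParams("full", stripped), K, c)
        np.testing.assert_allclose(V, V0, atol=1e-14)


class TestRemlLoglik:
    def _instance(self, seed, n=30):
        rng = np.random.default_rng(seed)
        g = mrnm.simulate_genotypes(n, 120, seed=seed + 50)
        K = mrnm.compute_grm(g)
        c = standardize(rng.standard_normal(n))
        y = rng.standard_normal(2 * n)
        return rng, K, c, y

    def test_translation_invariance(self):
        rng, K, c, y = self._instance(2)
        p = _random_params(rng)
        X = default_design(K.n)
        ll = reml_loglik(p, K, c, y, X)
        ll2 = reml_loglik(p, K, c, y + X @ np.array([3.7, -1.2]), X)
        assert ll2 == pytest.approx(ll, abs=1e-8)

    def test_permutation_invariance(self):
        rng, K, c, y = self._instance(3)
        p = _random_params(rng)
        n = K.n
        perm = rng.permutation(n)
        ll = reml_loglik(p, K.matrix, c, y)
        ll2 = reml_loglik(
            p,
            K.matrix[np.ix_(perm, perm)],
            c[perm],
            np.concatenate([y[:n][perm], y[n:][perm]]),
        )
        assert ll2 == pytest.approx(ll, abs=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_error_contrast_oracle(self, seed):
        # independent evaluation: project onto an orthonormal basis of
        # null(X') and take the Gaussian log-density of the contrasts
        rng, K, c, y = self._instance(seed + 10)
        p = _random_params(rng)
        X = default_design(K.n)
        A = null_space(X.T)
        V = build_covariance(p, K, c)
        M = A.T @ V @ A
        _, ld = np.linalg.slogdet(M)
        quad = y @ A @ np.linalg.solve(M, A.T @ y)
        oracle = -0.5 * (ld + quad) - 0.5 * np.linalg.slogdet(X.T @ X)[1]
        assert reml_loglik(p, K, c, y, X) == pytest.approx(oracle, abs=1e-8)

    def test_non_pd_is_signalled(self):
        _, K, c, y = self._instance(4)
        vals = np.zeros(12)
        vals[0] = -5.0  # wildly negative genetic variance
        vals[6] = 0.01
        vals[11] = 0.01
        with pytest.raises(NotPositiveDefiniteError):
            reml_loglik(MRNMParams("full", vals), K, c, y)


class TestFit:
    def test_nesting_full_at_least_null(self):
        _, _, _, _, fits = simulate_and_fit(
            150, 150, dict(var_a0=0.3, var_a1=0.0, var_t0=0.7, var_t1=0.0),
            seed=21, fit_kwargs={"min_n": 50},
        )
        assert fits["full"].loglik >= fits["null"].loglik - 1e-6

    def test_independent_traits_give_null_components(self):
        # Y and C unlinked, sigma_g = 0: polygenic variance ~ 0,
        # residual variance ~ 1, cross-covariances ~ 0, all within 2 SE
        _, _, _, _, fits = simulate_and_fit(
            400, 300,
            dict(var_a0=0.0, var_a1=0.0, var_t0=1.0, var_t1=0.0,
                 var_b0=0.0, var_e0=1.0),
            seed=22, model="null", fit_kwargs={"min_n": 50},
        )
        fit = fits["null"]
        for name, truth in [("var_a0", 0.0), ("var_t0", 1.0),
                            ("cov_a0b0", 0.0), ("cov_t0e0", 0.0)]:
            est, se = fit.estimate(name), fit.se_of(name)
            assert abs(est - truth) < 2.5 * se, (name, est, se)

    def test_small_instance_matches_direct_maximization(self):
        # the AI optimum of the null model (always interior at this size)
        # must not be improvable by a derivative-free simplex polish
        from scipy.optimize import minimize

        _, grm, Y, C, fits = simulate_and_fit(
            80, 200, dict(var_a0=0.3, var_a1=0.1, var_t0=0.5, var_t1=0.1),
            seed=23, model="null", fit_kwargs={"min_n": 10, "max_iter": 200},
        )
        fit = fits["null"]
        y = np.concatenate([Y.values, C.values])
        from mrnm.core import _Structure, _reml_pieces

        structure = _Structure(grm.matrix, C.values, "null")
        X = default_design(grm.n)

        def negll(t):
            try:
                return -_reml_pieces(structure.build_V(t), X, y,
                                     min_pivot=0.1)[-1]
            except NotPositiveDefiniteError:
                return 1e8

        polish = minimize(negll, fit.params.values, method="Nelder-Mead",
                          options=dict(maxfev=6000, fatol=1e-10, xatol=1e-8))
        assert -polish.fun <= fit.loglik + 1e-3

    def test_loglik_at_truth_not_above_fit(self):
        components = dict(var_a0=0.3, var_a1=0.1, var_t0=0.5, var_t1=0.1)
        study, grm, Y, C, fits = simulate_and_fit(
            120, 200, components, seed=24, model="full",
            fit_kwargs={"min_n": 10},
        )
        truth = MRNMParams.from_matrices(study.truth.sigma_g, study.truth.sigma_e)
        y = np.concatenate([Y.values, C.values])
        ll_truth = reml_loglik(truth, grm, C.values, y)
        assert fits["full"].loglik >= ll_truth - 1e-6

    def test_too_few_individuals_rejected(self, small_grm):
        with pytest.raises(ParameterError):
            mrnm.fit_mrnm(small_grm, np.zeros(120), np.zeros(120),
                          min_n=500)


def _fake_fit(values, se, model="full"):
    q = len(values)
    return MRNMFit(
        params=MRNMParams(model, np.asarray(values, dtype=float)),
        se=np.asarray(se, dtype=float),
        loglik=0.0,
        ai_matrix=np.eye(q),
        ai_inverse=np.diag(np.asarray(se, dtype=float) ** 2),
        converged=True,
        n_iter=1,
        n=1000,
    )


class TestVarianceReporting:
    def test_sleep_like_interval(self):
        # a 1.22% component with SE 0.344% has the familiar symmetric
        # normal 95% CI of roughly [0.54, 1.89]
        vals = np.zeros(12)
        ses = np.full(12, 0.01)
        vals[FULL_PARAMS.index("var_a1")] = 0.0122
        ses[FULL_PARAMS.index("var_a1")] = 0.00344
        props = variance_proportions(_fake_fit(vals, ses))
        lo, hi = props["var_a1"]["ci"]
        assert lo == pytest.approx(0.54, abs=0.015)
        assert hi == pytest.approx(1.89, abs=0.015)
        assert props["var_a1"]["excludes_zero"]

    def test_components_map_to_percentages(self):
        vals = np.zeros(12)
        vals[[0, 2, 6, 8]] = [0.2, 0.05, 0.7, 0.05]
        props = variance_proportions(_fake_fit(vals, np.full(12, 0.01)))
        got = [props[k]["pct"] for k in ("var_a0", "var_a1", "var_t0", "var_t1")]
        np.testing.assert_allclose(got, [20.0, 5.0, 70.0, 5.0])
        assert sum(got) == pytest.approx(100.0)

    def test_zero_component_ci_straddles_zero(self):
        vals = np.zeros(12)
        props = variance_proportions(_fake_fit(vals, np.full(12, 0.01)))
        assert not props["var_a1"]["excludes_zero"]

    def test_curve_at_zero_gradient_is_intercept_variance(self):
        vals = np.zeros(12)
        vals[[0, 2, 6, 8]] = [0.04, 0.0122, 0.7, 0.05]
        curve = variance_function(_fake_fit(vals, np.full(12, 0.01)),
                                  np.array([0.0]))
        assert curve.var_genetic[0] == pytest.approx(0.04, abs=1e-15)

    def test_curve_even_symmetry_without_intercept_slope_covariance(self):
        vals = np.zeros(12)
        vals[[0, 2, 6, 8]] = [0.04, 0.0122, 0.7, 0.05]
        grid = np.linspace(-2, 2, 9)
        curve = variance_function(_fake_fit(vals, np.full(12, 0.01)), grid)
        np.testing.assert_allclose(curve.var_genetic, curve.var_genetic[::-1],
                                   atol=1e-14)
        # U-shape: minimum at c = 0
        assert curve.var_genetic.argmin() == 4

    def test_curve_substitution_value(self):
        # var_g(2) = 0.04 + 0 + 4 * 0.0122 = 0.0888
        vals = np.zeros(12)
        vals[[0, 2]] = [0.04, 0.0122]
        curve = variance_function(_fake_fit(vals, np.full(12, 0.01)),
                                  np.array([2.0]))
        assert curve.var_genetic[0] == pytest.approx(0.0888, abs=1e-12)

    def test_extrapolation_flagged(self):
        vals = np.zeros(12)
        vals[[0, 6]] = [0.2, 0.8]
        curve = variance_function(
            _fake_fit(vals, np.full(12, 0.01)),
            np.array([-3.0, 0.0, 3.0]),
            c_observed=np.array([-2.0, 2.0]),
        )
        assert curve.extrapolated.tolist() == [True, False, True]
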