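"""Fractional-polynomial adjustment, standardization and RINT oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import skew

from mrnm.covariate_prep import (
    _fp_basis,
    adjust_and_standardize,
    fit_fixed_effects_fp,
    rint,
    transform_biomarker,
)
from mrnm.errors import DegenerateTraitError, ParameterError, ValidationError


def _design(**cols):
    return pd.DataFrame(cols)


class TestFractionalPolynomials:
    def test_ln_at_e_is_one(self):
        x = np.array([np.e, np.e ** 2])
        basis = _fp_basis(x, (0.0,), shift=0.0)
        np.testing.assert_allclose(basis[:, 0], [1.0, 2.0])

    def test_repeated_power_adds_log_column(self):
        x = np.array([2.0, 4.0])
        basis = _fp_basis(x, (2.0, 2.0), shift=0.0)
        np.testing.assert_allclose(basis[:, 0], x ** 2)
        np.testing.assert_allclose(basis[:, 1], x ** 2 * np.log(x))

    def test_linear_truth_selects_linear(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 10, size=5000)
        y = 2.0 * x + rng.standard_normal(5000)
        model = fit_fixed_effects_fp(y, _design(x=x), fp_columns=["x"])
        assert model.selected["x"] == (1.0,)

    def test_quadratic_truth_recovers_square_or_equivalent_fit(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(1, 10, size=5000)
        y = x ** 2 + 0.5 * rng.standard_normal(5000)
        model = fit_fixed_effects_fp(y, _design(x=x), fp_columns=["x"])
        assert model.selected["x"] != (1.0,)
        if 2.0 not in model.selected["x"]:
            # an FP pair may tie; its fit must match the x^2 oracle closely
            oracle = np.column_stack([np.ones_like(x), x ** 2])
            beta, *_ = np.linalg.lstsq(oracle, y, rcond=None)
            rss_oracle = float(((y - oracle @ beta) ** 2).sum())
            tss = float(((y - y.mean()) ** 2).sum())
            assert model.r_squared >= (1 - rss_oracle / tss) - 0.005

    def test_null_covariate_usually_dropped(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1, 5, size=2000)
        y = rng.standard_normal(2000)
        model = fit_fixed_effects_fp(y, _design(x=x), fp_columns=["x"])
        assert model.selected["x"] == ()

    def test_few_distinct_values_demoted_with_warning(self):
        rng = np.random.default_rng(3)
        x = rng.choice([0.0, 1.0], size=200)
        y = x + rng.standard_normal(200)
        with pytest.warns(UserWarning, match="demoted"):
            model = fit_fixed_effects_fp(y, _design(x=x), fp_columns=["x"])
        assert model.selected["x"] == (1.0,)

    def test_closed_test_controls_its_level(self):
        # under a true null, a linear-or-nonlinear term should be selected
        # in roughly alpha of replicates
        rng = np.random.default_rng(4)
        hits = 0
        reps = 60
        for _ in range(reps):
            x = rng.uniform(1, 5, size=250)
            y = rng.standard_normal(250)
            model = fit_fixed_effects_fp(y, _design(x=x), fp_columns=["x"],
                                         alpha=0.05)
            hits += model.selected["x"] != ()
        # exact binomial 99% interval for Binomial(60, 0.05)
        assert 0 <= hits <= 9


class TestAdjustStandardize:
    def test_output_mean_zero_variance_one(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 10, size=400)
        y = 1.0 + 0.5 * x + rng.standard_normal(400)
        model = fit_fixed_effects_fp(y, _design(x=x))
        adj = adjust_and_standardize(y, model)
        assert abs(adj.values.mean()) < 1e-10
        assert adj.values.var(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 10, size=300)
        z = rng.standard_normal(300)
        y = x - z + rng.standard_normal(300)
        model = fit_fixed_effects_fp(y, _design(x=x, z=z))
        adj = adjust_and_standardize(y, model)
        assert abs(adj.values @ x) < 1e-6 * np.linalg.norm(x) * 300
        assert abs(adj.values @ z) < 1e-6 * 300

    def test_five_point_hand_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 1.0, 3.0, 3.0])
        # hand arithmetic: xbar=3, ybar=2, Sxy=5, Sxx=10 -> slope 0.5,
        # intercept 2 - 0.5*3 = 0.5
        resid = y - (0.5 + 0.5 * x)
        expected = (resid - resid.mean()) / resid.std(ddof=0)
        model = fit_fixed_effects_fp(y, _design(x=x))
        adj = adjust_and_standardize(y, model)
        np.testing.assert_allclose(adj.values, expected, atol=1e-10)

    def test_idempotence_of_readjustment(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 5, size=500)
        y = x ** 2 + rng.standard_normal(500)
        m1 = fit_fixed_effects_fp(y, _design(x=x))
        a1 = adjust_and_standardize(y, m1)
        m2 = fit_fixed_effects_fp(a1.values, _design(x=x))
        a2 = adjust_and_standardize(a1.values, m2)
        np.testing.assert_allclose(a2.values, a1.values, atol=1e-8)

    def test_constant_trait_is_degenerate(self):
        x = np.arange(10.0)
        y = 3.0 + 2.0 * x  # exactly fitted -> zero residual variance
        model = fit_fixed_effects_fp(y, _design(x=x))
        with pytest.raises(DegenerateTraitError):
            adjust_and_standardize(y, model)


class TestTransformsAndRint:
    def test_log_rule(self):
        np.testing.assert_allclose(transform_biomarker(np.array([1.0]), "log"), [0.0])
        v = np.array([2.0, 5.0])
        np.testing.assert_allclose(transform_biomarker(v, "identity"), v)
        with pytest.raises(ValidationError):
            transform_biomarker(np.array([1.0, -2.0]), "log")
        with pytest.raises(ParameterError):
            transform_biomarker(v, "sqrt")

    def test_rint_three_values_blom_oracle(self):
        # quantiles at (r - 3/8)/(n + 1/4) = 0.1923, 0.5, 0.8077
        out = rint(np.array([10.0, 20.0, 30.0]))
        np.testing.assert_allclose(out, [-0.8694, 0.0, 0.8694], atol=1e-4)

    def test_rint_monotone_and_symmetric(self):
        rng = np.random.default_rng(8)
        v = rng.exponential(size=101)
        out = rint(v)
        assert (np.argsort(out) == np.argsort(v)).all()
        assert out.mean() == pytest.approx(0.0, abs=1e-12)

    def test_rint_normalises_any_input(self):
        rng = np.random.default_rng(9)
        v = rng.exponential(size=2000) ** 2
        assert abs(skew(rint(v))) < 0.05

    def test_rint_constant_input_degenerate(self):
        with pytest.raises(DegenerateTraitError):
            rint(np.ones(10))
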