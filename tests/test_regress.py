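"""OLS statistics, leave-one-out Q2 and prediction, against independent
oracles (explicit normal equations, explicit refits, statsmodels)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hqsar.regress import (
    CollinearityError,
    LinearModel,
    Term,
    fit_ols,
    loo_q2,
    predict,
)


def _normal_equations_oracle(X, y):
    """Explicit (X'X)^-1 X'y with the textbook statistics."""
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    XtX_inv = np.linalg.inv(A.T @ A)
    b = XtX_inv @ A.T @ y
    resid = y - A @ b
    rss = resid @ resid
    tss = np.sum((y - y.mean()) ** 2)
    r2 = 1 - rss / tss
    s2 = rss / (n - k - 1)
    se = np.sqrt(s2 * np.diag(XtX_inv))
    f = (r2 / k) / ((1 - r2) / (n - k - 1))
    return b, se, r2, s2, f


def _loo_refit_oracle(X, y):
    n, k = X.shape
    A = np.column_stack([np.ones(n), X])
    press = 0.0
    for i in range(n):
        keep = np.arange(n) != i
        b = np.linalg.lstsq(A[keep], y[keep], rcond=None)[0]
        press += (y[i] - A[i] @ b) ** 2
    return 1 - press / np.sum((y - y.mean()) ** 2)


class TestFitOls:
    def test_noiseless_line(self):
        x = np.arange(6.0)
        m = fit_ols(x, 1 + 2 * x)
        assert m.intercept == pytest.approx(1, abs=1e-12)
        assert m.terms[0].coef == pytest.approx(2, abs=1e-12)
        assert m.r2 == pytest.approx(1, abs=1e-14)
        assert m.s2 == pytest.approx(0, abs=1e-20)
        assert np.isinf(m.f_stat) and np.isinf(m.terms[0].t)

    def test_constant_response_convention(self, rng):
        X = rng.standard_normal((8, 2))
        with pytest.warns(UserWarning, match="zero variance"):
            m = fit_ols(X, np.full(8, 3.5))
        assert m.r2 == 0 and m.q2 == 0
        assert all(t.coef == 0 for t in m.terms)
        assert m.intercept == pytest.approx(3.5)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.standard_normal((12, 3))
        y = 1 + X @ np.array([0.5, -2.0, 1.0]) + 0.3 * rng.standard_normal(12)
        m = fit_ols(X, y)
        b, se, r2, s2, f = _normal_equations_oracle(X, y)
        assert m.intercept == pytest.approx(b[0], abs=1e-10)
        np.testing.assert_allclose(m.coefs, b[1:], atol=1e-10)
        np.testing.assert_allclose(
            [t.se for t in m.terms], se[1:], atol=1e-10
        )
        np.testing.assert_allclose(
            [t.t for t in m.terms], np.abs(b[1:]) / se[1:], atol=1e-10
        )
        assert m.r2 == pytest.approx(r2, abs=1e-10)
        assert m.s2 == pytest.approx(s2, abs=1e-10)
        assert m.f_stat == pytest.approx(f, abs=1e-8)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        X = rng.standard_normal((15, 4))
        y = 2 - X[:, 0] + 3 * X[:, 2] + rng.standard_normal(15)
        m = fit_ols(X, y)
        res = sm.OLS(y, sm.add_constant(X)).fit()
        np.testing.assert_allclose(
            np.r_[m.intercept, m.coefs], res.params, atol=1e-10
        )
        np.testing.assert_allclose(
            [m.intercept_se] + [t.se for t in m.terms], res.bse, atol=1e-10
        )
        assert m.r2 == pytest.approx(res.rsquared, abs=1e-12)
        assert m.f_stat == pytest.approx(res.fvalue, abs=1e-8)

    def test_simple_regression_closed_form(self, rng):
        x = rng.standard_normal(20)
        y = 3 + 0.7 * x + 0.1 * rng.standard_normal(20)
        m = fit_ols(x, y)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert m.terms[0].coef == pytest.approx(slope, abs=1e-12)
        assert m.intercept == pytest.approx(y.mean() - slope * x.mean(), abs=1e-12)

    def test_rank_deficiency_names_collinear_columns(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 2] = 2 * X[:, 0]
        with pytest.raises(CollinearityError) as exc:
            fit_ols(X, rng.standard_normal(10), names=["a", "b", "c"])
        assert exc.value.columns  # at least one offender identified

    def test_too_few_compounds_rejected(self, rng):
        with pytest.raises(ValueError, match="n >= k \\+ 2"):
            fit_ols(rng.standard_normal((4, 3)), rng.standard_normal(4))

    def test_adding_descriptor_never_decreases_r2(self, rng):
        X = rng.standard_normal((14, 4))
        y = X[:, 0] + rng.standard_normal(14)
        r2 = [fit_ols(X[:, : k + 1], y).r2 for k in range(4)]
        assert all(b >= a - 1e-12 for a, b in zip(r2, r2[1:]))

    @given(c=st.floats(min_value=1e-3, max_value=1e3), sign=st.sampled_from([-1, 1]))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_scale_equivariance(self, c, sign):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((12, 2))
        y = 1 + X @ [2.0, -1.0] + 0.2 * rng.standard_normal(12)
        base = fit_ols(X, y)
        scaled = X.copy()
        scaled[:, 0] *= sign * c
        m = fit_ols(scaled, y)
        assert m.terms[0].coef == pytest.approx(base.terms[0].coef / (sign * c), rel=1e-9)
        assert m.terms[0].se == pytest.approx(base.terms[0].se / c, rel=1e-9)
        assert m.terms[0].t == pytest.approx(base.terms[0].t, rel=1e-9)
        assert m.r2 == pytest.approx(base.r2, abs=1e-10)
        assert m.f_stat == pytest.approx(base.f_stat, rel=1e-9)
        assert m.q2 == pytest.approx(base.q2, abs=1e-10)

    def test_permutation_invariance(self, rng):
        X = rng.standard_normal((13, 3))
        y = X @ [1.0, 0.5, -0.5] + 0.3 * rng.standard_normal(13)
        base = fit_ols(X, y)
        perm = rng.permutation(13)
        m = fit_ols(X[perm], y[perm])
        np.testing.assert_allclose(m.coefs, base.coefs, atol=1e-10)
        assert m.r2 == pytest.approx(base.r2, abs=1e-12)
        assert m.q2 == pytest.approx(base.q2, abs=1e-10)


class TestLooQ2:
    def test_noiseless_data_gives_q2_of_1(self):
        x = np.arange(8.0)
        assert loo_q2(x, 2 * x - 1) == pytest.approx(1, abs=1e-12)

    def test_hat_shortcut_equals_explicit_refits(self, rng):
        X = rng.standard_normal((15, 3))
        y = X @ [1.0, -0.5, 2.0] + rng.standard_normal(15)
        assert loo_q2(X, y) == pytest.approx(_loo_refit_oracle(X, y), abs=1e-10)

    def test_q2_never_exceeds_r2(self, rng):
        for _ in range(10):
            X = rng.standard_normal((12, 3))
            y = X[:, 0] + rng.standard_normal(12)
            m = fit_ols(X, y)
            assert m.q2 <= m.r2 + 1e-12

    def test_needs_three_spare_compounds(self, rng):
        with pytest.raises(ValueError, match="k \\+ 3"):
            loo_q2(rng.standard_normal((5, 3)), rng.standard_normal(5))


class TestPredict:
    def test_arithmetic(self):
        m = LinearModel(
            intercept=1.0, intercept_se=0.0, intercept_t=0.0,
            terms=[Term("x", 2.0, 0.0, 0.0)], n=6, r2=1.0, s2=0.0,
            f_stat=np.inf, q2=1.0,
        )
        assert predict(m, np.array([3.0]))[0] == pytest.approx(7.0)

    def test_reproduces_fitted_values(self, rng):
        X = rng.standard_normal((10, 2))
        y = X @ [1.5, -2.0] + rng.standard_normal(10)
        m = fit_ols(X, y, names=["a", "b"])
        fitted = predict(m, pd.DataFrame(X, columns=["a", "b"]))
        rss = np.sum((y - fitted) ** 2)
        assert m.s2 * (10 - 2 - 1) == pytest.approx(rss, rel=1e-10)

    def test_dot_product_oracle_on_fresh_rows(self, rng):
        X = rng.standard_normal((10, 3))
        y = X @ [1.0, 2.0, 3.0] + rng.standard_normal(10)
        m = fit_ols(X, y, names=list("abc"))
        rows = rng.standard_normal((4, 3))
        expect = m.intercept + rows @ m.coefs
        got = predict(m, pd.DataFrame(rows, columns=list("abc")))
        np.testing.assert_allclose(got, expect, atol=1e-12)

    def test_missing_term_named_in_error(self, rng):
        X = rng.standard_normal((10, 2))
        m = fit_ols(X, rng.standard_normal(10), names=["a", "b"])
        with pytest.raises(KeyError, match="b"):
            predict(m, pd.DataFrame({"a": [1.0]}))


class TestSerialization:
    def test_json_round_trip(self, rng):
        X = rng.standard_normal((10, 2))
        m = fit_ols(X, rng.standard_normal(10), names=["a", "b"])
        back = LinearModel.from_dict(m.to_dict())
        assert back == m

    def test_layout_mirrors_model_listing(self, rng):
        X = rng.standard_normal((10, 2))
        m = fit_ols(X, rng.standard_normal(10), names=["a", "b"])
        d = m.to_dict()
        assert d["rows"][0]["name"] == "Intercept"
        assert [r["row"] for r in d["rows"]] == [0, 1, 2]
        assert set(d) >= {"N", "R2", "F", "s2", "Q2", "size"}
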