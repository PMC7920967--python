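import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from patchmorph.simulate import SimulationSpec, simulate_covariates
from patchmorph.stats import (
    Contrast,
    CovariateTable,
    build_design,
    fit_glm,
    sse_ratio,
)


@pytest.fixture
def cov35() -> CovariateTable:
    return simulate_covariates(SimulationSpec(seed=1), np.random.default_rng(1))


class TestBuildDesign:
    def test_nr_vs_r_is_14_by_5(self, cov35):
        X, names, mask = build_design(cov35, Contrast("NR_vs_R"))
        assert X.shape == (14, 5)
        assert names == ["intercept", "age", "sex", "icv", "response"]
        assert X[:, 4].sum() == 5  # five non-responders

    def test_nr_vs_all_is_35_by_5(self, cov35):
        X, _, mask = build_design(cov35, Contrast("NR_vs_HCandR"))
        assert X.shape == (35, 5)
        assert X[:, 4].sum() == 5
        assert mask.all()

    def test_without_response_four_columns(self, cov35):
        X, names, _ = build_design(cov35, Contrast("NR_vs_R"), with_response=False)
        assert X.shape == (14, 4)
        assert "response" not in names

    def test_collinear_column_named(self):
        df = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(8)],
                "age": np.array([23, 41, 30, 55, 28, 47, 33, 60], float),
                "sex": np.ones(8),  # constant -> collinear with intercept
                "icv": np.array([1.41, 1.55, 1.38, 1.62, 1.47, 1.52, 1.44, 1.58]) * 1e6,
                "group": ["R"] * 4 + ["NR"] * 4,
            }
        )
        with pytest.raises(ValueError, match="sex"):
            build_design(CovariateTable(df), Contrast("NR_vs_R"))


class TestFitGlm:
    def test_exact_linear_data_zero_sse(self, rng):
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 3))])
        beta_true = np.array([1.0, -0.5, 2.0, 0.25])
        Y = (X @ beta_true)[None, :]
        fit = fit_glm(Y, X)
        assert fit.sse[0] == pytest.approx(0.0, abs=1e-18)
        assert fit.beta[0] == pytest.approx(beta_true, abs=1e-9)

    def test_intercept_only_gives_centered_sum_of_squares(self, rng):
        y = rng.normal(size=(3, 15))
        fit = fit_glm(y, np.ones((15, 1)))
        assert fit.sse == pytest.approx(((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1))

    def test_matches_normal_equations_oracle(self, rng):
        X = np.column_stack([np.ones(12), rng.normal(size=(12, 3))])
        Y = rng.normal(size=(4, 12))
        fit = fit_glm(Y, X)
        oracle = np.linalg.solve(X.T @ X, X.T @ Y.T).T
        assert np.allclose(fit.beta, oracle, atol=1e-9)

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError):
            fit_glm(rng.normal(size=(2, 3)), rng.normal(size=(3, 5)))


class TestSseRatio:
    def test_at_least_one(self, cov35, rng):
        X_alt, _, mask = build_design(cov35, Contrast("NR_vs_R"))
        Y = rng.normal(size=(9, int(mask.sum())))
        s = sse_ratio(Y, X_alt[:, :-1], X_alt)
        assert np.all(s >= 1.0)

    def test_equals_one_when_response_uninformative(self, cov35):
        """Y generated exactly from the null model: adding the response
        column cannot reduce a zero residual."""
        X_alt, _, mask = build_design(cov35, Contrast("NR_vs_R"))
        X_null = X_alt[:, :-1]
        Y = (X_null @ np.array([1.0, 0.01, -0.02, 1e-8]))[None, :]
        s = sse_ratio(Y, X_null, X_alt)
        assert s[0] == pytest.approx(1.0)

    def test_partial_f_identity_against_statsmodels(self, cov35, rng):
        """s_p = 1 + F/(n - p_alt), F the partial F test for response."""
        import statsmodels.api as sm

        X_alt, _, mask = build_design(cov35, Contrast("NR_vs_R"))
        n, p_alt = X_alt.shape
        Y = 1.0 + 0.05 * rng.normal(size=(6, n))
        s = sse_ratio(Y, X_alt[:, :-1], X_alt)
        for p in range(6):
            res = sm.OLS(Y[p], X_alt).fit()
            F = float(res.f_test(np.eye(p_alt)[-1]).fvalue)
            assert s[p] == pytest.approx(1.0 + F / (n - p_alt), abs=1e-9)

    def test_perfect_alternative_fit_is_infinite(self, cov35):
        X_alt, _, mask = build_design(cov35, Contrast("NR_vs_R"))
        Y = (X_alt @ np.array([1.0, 0.0, 0.0, 0.0, -0.15]))[None, :]
        with pytest.warns(RuntimeWarning, match="inf"):
            s = sse_ratio(Y, X_alt[:, :-1], X_alt)
        assert np.isinf(s[0])

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(a=st.floats(min_value=0.1, max_value=50), b=st.floats(min_value=-10, max_value=10))
    def test_affine_invariance_of_statistic(self, a, b):
        """s_p is unchanged by y -> a*y + b (the design has an intercept)."""
        rng = np.random.default_rng(3)
        cov = simulate_covariates(SimulationSpec(seed=3), rng)
        X_alt, _, _ = build_design(cov, Contrast("NR_vs_R"))
        Y = 1.0 + 0.05 * rng.normal(size=(3, X_alt.shape[0]))
        s0 = sse_ratio(Y, X_alt[:, :-1], X_alt)
        s1 = sse_ratio(a * Y + b, X_alt[:, :-1], X_alt)
        assert s1 == pytest.approx(s0, rel=1e-9)
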