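"""OLS of congruence on covariates: recovery, standardization identity,
inference calibration and the correlation matrix."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crowdcongruence.model import COVARIATE_COLUMNS
from crowdcongruence.regression import (
    correlation_matrix,
    fit_ols,
    standardize_and_fit,
)
from crowdcongruence.simulate import SimulationConfig, simulate_district_study


def _design(n=29, k=6, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.normal(size=(n, k)), columns=[f"x{i}" for i in range(k)]
    )
    return rng, X


def test_exact_recovery_in_noiseless_limit():
    rng, X = _design(seed=1)
    beta = np.array([0.5, -1.0, 2.0, 0.0, 0.3, -0.7])
    y = pd.Series(1.5 + X.to_numpy() @ beta, index=X.index)
    res = fit_ols(X, y, dependent="y")
    assert res.params["const"] == pytest.approx(1.5, abs=1e-8)
    for name, b in zip(X.columns, beta):
        assert res.params[name] == pytest.approx(b, abs=1e-8)
    assert res.r2 == pytest.approx(1.0)


def test_standardized_coefficients_identity():
    rng, X = _design(seed=2)
    y = pd.Series(rng.normal(size=len(X)) + X["x0"], index=X.index)
    res = fit_ols(X, y, dependent="y")
    sy = y.std(ddof=1)
    for name in X.columns:
        expected = res.params[name] * X[name].std(ddof=1) / sy
        assert res.standardized[name] == pytest.approx(expected, abs=1e-10)
    assert "const" not in res.standardized.index


def test_standardized_fit_intercept_is_zero():
    import statsmodels.api as sm

    rng, X = _design(seed=3)
    y = pd.Series(rng.normal(size=len(X)), index=X.index)
    Xz = (X - X.mean()) / X.std(ddof=1)
    yz = (y - y.mean()) / y.std(ddof=1)
    refit = sm.OLS(yz, sm.add_constant(Xz)).fit()
    assert abs(refit.params["const"]) < 1e-10


def test_one_sd_shift_moves_prediction_by_standardized_beta():
    rng, X = _design(seed=4)
    y = pd.Series(rng.normal(size=len(X)) + 0.8 * X["x1"], index=X.index)
    res = fit_ols(X, y, dependent="y")
    # raw prediction change for a 1-SD covariate shift, in SDs of y
    delta = res.params["x1"] * X["x1"].std(ddof=1) / y.std(ddof=1)
    assert delta == pytest.approx(res.standardized["x1"], abs=1e-12)


def test_affine_rescaling_invariance():
    """Multiplying a covariate by a constant (the density-unit choice)
    leaves p-values and standardized coefficients unchanged."""
    rng, X = _design(seed=5)
    y = pd.Series(rng.normal(size=len(X)) + X["x2"], index=X.index)
    res = fit_ols(X, y, dependent="y")
    X2 = X.copy()
    X2["x2"] = X2["x2"] * 1e6
    res2 = fit_ols(X2, y, dependent="y")
    assert res2.pvalues["x2"] == pytest.approx(res.pvalues["x2"], rel=1e-9)
    assert res2.standardized["x2"] == pytest.approx(res.standardized["x2"], rel=1e-9)
    assert res2.params["x2"] == pytest.approx(res.params["x2"] / 1e6, rel=1e-9)


def test_residuals_orthogonal_to_design():
    rng, X = _design(seed=6)
    y = pd.Series(rng.normal(size=len(X)) + X.sum(axis=1), index=X.index)
    res = fit_ols(X, y, dependent="y")
    fitted = res.params["const"] + X.to_numpy() @ res.params[X.columns].to_numpy()
    resid = y.to_numpy() - fitted
    assert abs(resid.sum()) < 1e-8
    for col in X.columns:
        assert abs(resid @ X[col].to_numpy()) < 1e-8


def test_adjusted_r2_below_r2():
    rng, X = _design(seed=7)
    y = pd.Series(rng.normal(size=len(X)) + X["x0"], index=X.index)
    res = fit_ols(X, y, dependent="y")
    assert res.adjusted_r2 <= res.r2 <= 1.0
    n, k = len(X), X.shape[1]
    assert res.adjusted_r2 == pytest.approx(
        1 - (1 - res.r2) * (n - 1) / (n - k - 1), abs=1e-12
    )


def test_collinear_design_rejected_naming_columns():
    rng, X = _design(seed=8)
    X["x5"] = 2.0 * X["x0"]
    y = pd.Series(rng.normal(size=len(X)), index=X.index)
    with pytest.raises(ValueError, match="x0~x5"):
        fit_ols(X, y, dependent="y")


def test_constant_dependent_rejected():
    _, X = _design(seed=9)
    y = pd.Series(0.3, index=X.index)
    with pytest.raises(ValueError, match="zero variance"):
        fit_ols(X, y, dependent="y")


def test_zero_variance_covariate_rejected():
    rng, X = _design(seed=10)
    X["x3"] = 1.0
    y = pd.Series(rng.normal(size=len(X)), index=X.index)
    with pytest.raises(ValueError):
        standardize_and_fit(X, y)


def test_missing_congruence_dropped_listwise():
    rng, X = _design(n=31, seed=11)
    y = pd.Series(rng.normal(size=len(X)) + X["x0"], index=X.index)
    y.iloc[3] = np.nan
    y.iloc[17] = np.nan
    res = fit_ols(X, y, dependent="y")
    assert res.n_obs == 29
    assert len(res.dropped_districts) == 2


def test_type_one_error_rate_calibrated():
    """Pure-noise dependent: the 0.05-level rejection rate over 1000
    replicates stays within 3 binomial SEs of 5%."""
    rng = np.random.default_rng(2024)
    rejections = 0
    n_rep = 1000
    for _ in range(n_rep):
        X = pd.DataFrame(rng.normal(size=(29, 6)), columns=[f"x{i}" for i in range(6)])
        y = pd.Series(rng.normal(size=29), index=X.index)
        res = fit_ols(X, y, dependent="y")
        rejections += res.pvalues["x0"] < 0.05
    rate = rejections / n_rep
    se = np.sqrt(0.05 * 0.95 / n_rep)
    assert abs(rate - 0.05) < 3 * se


def test_correlation_matrix_against_independent_computation():
    rng, X = _design(seed=12)
    r, p = correlation_matrix(X)
    oracle = np.corrcoef(X.to_numpy(), rowvar=False)
    assert np.allclose(r.to_numpy(), oracle, atol=1e-12)
    assert np.allclose(np.diag(r), 1.0)
    # p-values via the t transform, independently
    n = len(X)
    for a in X.columns:
        for b in X.columns:
            if a >= b:
                continue
            rv = r.loc[a, b]
            t = rv * np.sqrt((n - 2) / (1 - rv**2))
            expected = 2 * stats.t.sf(abs(t), df=n - 2)
            assert p.loc[a, b] == pytest.approx(expected, rel=1e-9)


def test_correlation_matrix_collinear_pair():
    _, X = _design(seed=13)
    X["x1"] = -3.0 * X["x0"]
    r, _ = correlation_matrix(X)
    assert r.loc["x0", "x1"] == pytest.approx(-1.0)


def test_dependent_swap_reproduces_signs():
    """Fitting on rho instead of tau goes through the same path and gives
    a sign-concordant birthrate effect on generator output."""
    config = SimulationConfig(
        n_districts=150, hospitals_per_district=12, threads_per_district=30, seed=14
    )
    df = simulate_district_study(config).dropna(subset=["kendall_tau", "spearman_rho"])
    features = df[COVARIATE_COLUMNS]
    res_tau = fit_ols(features, df["kendall_tau"], dependent="kendall_tau")
    res_rho = fit_ols(features, df["spearman_rho"], dependent="spearman_rho")
    assert res_tau.params["birthrate"] < 0
    assert res_rho.params["birthrate"] < 0
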