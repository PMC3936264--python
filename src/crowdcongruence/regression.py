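"""OLS analysis of congruence on the sociodemographic covariates.

The model is congruence_d = beta0 + x_d' beta + e_d over districts, with
Kendall tau (or Spearman rho) as the dependent variable and the six
covariates as regressors.  Reported alongside the raw fit: classical
standard errors, two-sided t-test p-values, adjusted R^2, and standardized
coefficients (all variables z-scored), which satisfy
beta_std_j = beta_j * SD(x_j) / SD(y).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RegressionResult",
    "fit_ols",
    "standardize_and_fit",
    "correlation_matrix",
]


@dataclass
class RegressionResult:
    """An OLS fit of a congruence index on district covariates."""

    dependent: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r2: float
    adjusted_r2: float
    standardized: pd.Series
    n_obs: int
    df_resid: int
    dropped_districts: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        """Coefficient table: coefficient, SE, P, standardized coefficient
        (blank for the intercept)."""
        rows = []
        for name in self.params.index:
            rows.append(
                {
                    "variable": name,
                    "coefficient": self.params[name],
                    "se": self.bse[name],
                    "p_value": self.pvalues[name],
                    "standardized": self.standardized.get(name, np.nan),
                }
            )
        return pd.DataFrame(rows).set_index("variable")

    def summary(self) -> str:
        lines = [
            f"OLS: {self.dependent} ~ {' + '.join(n for n in self.params.index if n != 'const')}",
            f"n = {self.n_obs}, adjusted R^2 = {self.adjusted_r2:.3f}",
        ]
        if self.dropped_districts:
            lines.append(
                f"dropped districts (missing congruence): {', '.join(self.dropped_districts)}"
            )
        lines.append(
            self.to_frame()
            .rename(columns={"p_value": "P"})
            .to_string(float_format=lambda v: f"{v: .4f}")
        )
        return "\n".join(lines)


def _check_design(X: pd.DataFrame) -> None:
    zero_var = [c for c in X.columns if np.isclose(X[c].std(ddof=0), 0.0)]
    if zero_var:
        raise ValueError(f"zero-variance covariates: {zero_var}")
    design = sm.add_constant(X.to_numpy(dtype=float))
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pairs = [
            f"{a}~{b}"
            for a in corr.index
            for b in corr.columns
            if a < b and corr.loc[a, b] > 1 - 1e-10
        ]
        raise ValueError(
            "design matrix is rank deficient"
            + (f"; collinear columns: {pairs}" if pairs else "")
        )


def fit_ols(
    features: pd.DataFrame,
    congruence: pd.Series,
    dependent: str = "kendall_tau",
) -> RegressionResult:
    """Least-squares fit of a congruence index on the covariates.

    Districts with missing (NaN) congruence are dropped listwise and
    logged.  Raises on a constant dependent (no variance to explain), a
    rank-deficient design, or too few observations.
    """
    y = congruence.reindex(features.index)
    keep = y.notna()
    dropped = [str(d) for d in y.index[~keep]]
    if dropped:
        logger.info(
            "dropping %d district(s) with undefined %s: %s",
            len(dropped),
            dependent,
            ", ".join(dropped),
        )
    X = features.loc[keep].astype(float)
    y = y.loc[keep].astype(float)
    k = X.shape[1]
    if len(y) < k + 2:
        raise ValueError(
            f"need more than {k + 1} districts to fit {k} covariates, have {len(y)}"
        )
    if np.isclose(y.std(ddof=0), 0.0):
        raise ValueError(f"dependent variable {dependent!r} has zero variance")
    _check_design(X)

    res = sm.OLS(y, sm.add_constant(X)).fit()
    standardized = standardize_and_fit(X, y)
    return RegressionResult(
        dependent=dependent,
        params=res.params,
        bse=res.bse,
        pvalues=res.pvalues,
        r2=float(res.rsquared),
        adjusted_r2=float(res.rsquared_adj),
        standardized=standardized,
        n_obs=int(res.nobs),
        df_resid=int(res.df_resid),
        dropped_districts=dropped,
    )


def standardize_and_fit(features: pd.DataFrame, congruence: pd.Series) -> pd.Series:
    """Standardized coefficients: z-score every variable (sample SD,
    ddof=1), refit, and return the slope coefficients.  The refit intercept
    is forced to zero by centering and is not returned."""
    X = features.astype(float)
    y = congruence.reindex(X.index).astype(float)
    sx = X.std(ddof=1)
    sy = y.std(ddof=1)
    if (sx == 0).any():
        raise ValueError(f"zero-variance covariates: {list(sx.index[sx == 0])}")
    if sy == 0:
        raise ValueError("dependent variable has zero variance")
    Xz = (X - X.mean()) / sx
    yz = (y - y.mean()) / sy
    res = sm.OLS(yz, sm.add_constant(Xz)).fit()
    return res.params.drop("const")


def correlation_matrix(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between covariates with two-sided
    p-values from the t transform.  Returns ``(r, p)`` DataFrames; a
    zero-variance column yields NaN entries with a warning."""
    if len(features) < 3:
        raise ValueError("need at least 3 districts for correlations")
    cols = list(features.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.full((len(cols), len(cols)), np.nan), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            xa = features[a].astype(float)
            xb = features[b].astype(float)
            if np.isclose(xa.std(ddof=0), 0) or np.isclose(xb.std(ddof=0), 0):
                logger.warning("zero variance in %s or %s; correlation undefined", a, b)
                r.loc[a, b] = r.loc[b, a] = np.nan
                continue
            rv, pv = stats.pearsonr(xa, xb)
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p
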