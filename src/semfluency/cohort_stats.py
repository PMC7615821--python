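"""Cohort-level statistics: exclusion filtering, OLS regression, correlation.

The cohort analysis regresses each fluency statistic (mean adjacent cosine
similarity; mean vector length) on self-rated language interest (SAMQ
language item, a Likert score in [-3, 3]), number of correct items, age and
gender, with an intercept.  Ordinary least squares with classical standard
errors and two-sided p-values from the t distribution with n - p residual
degrees of freedom; no correction across the two models.

``fit_ols`` and ``pearson_r`` are implemented from first principles (the
package's regression core is also reused voxelwise); tests check them
against independent oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RegressionResult",
    "apply_exclusions",
    "fit_ols",
    "fit_model",
    "pearson_r",
]


@dataclass(frozen=True)
class RegressionResult:
    """One OLS fit: estimates, classical SEs, t-ratios, two-sided p-values."""

    names: tuple[str, ...]
    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_resid: int
    n: int

    def to_frame(self) -> pd.DataFrame:
        """Regression table in the conventional layout (one row per term)."""
        return pd.DataFrame(
            {
                "term": self.names,
                "beta": self.beta,
                "se": self.se,
                "t": self.t,
                "p": self.p,
            }
        )

    def __getitem__(self, name: str) -> dict[str, float]:
        i = self.names.index(name)
        return {
            "beta": float(self.beta[i]),
            "se": float(self.se[i]),
            "t": float(self.t[i]),
            "p": float(self.p[i]),
        }


def apply_exclusions(
    roster: pd.DataFrame,
    age_max: float = 40.0,
    flag_columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Retain participants with no missing-data flag and age <= ``age_max``.

    The age boundary is inclusive: "over the age of 40" drops 41+, keeps 40.
    ``flag_columns`` defaults to every boolean column whose name starts with
    ``missing_``.
    """
    if "age" not in roster.columns:
        raise ValueError("roster is missing an 'age' column")
    if roster["age"].isna().any():
        missing = roster.loc[roster["age"].isna()].index.tolist()
        raise ValueError(f"missing age for roster rows {missing}")
    if flag_columns is None:
        flag_columns = [c for c in roster.columns if c.startswith("missing_")]
    keep = roster["age"] <= age_max
    for col in flag_columns:
        keep &= ~roster[col].astype(bool)
    return roster.loc[keep].reset_index(drop=True)


def fit_ols(
    y: np.ndarray, X: np.ndarray, names: Sequence[str] | None = None
) -> RegressionResult:
    """Ordinary least squares with classical standard errors.

    ``X`` is the full design matrix (include the intercept column yourself
    or use :func:`fit_model`).  Rank-deficient designs are rejected with the
    offending columns named.  Two-sided p-values come from the t
    distribution with ``n - p`` degrees of freedom.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D design matrix")
    n, p = X.shape
    if names is None:
        names = tuple(f"x{j}" for j in range(p))
    names = tuple(names)
    if len(names) != p:
        raise ValueError("names length must equal number of design columns")
    if y.shape[0] != n:
        raise ValueError("y length must equal number of design rows")
    if n <= p:
        raise ValueError(f"need n > p parameters (n={n}, p={p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        culprits = _collinear_columns(X, names)
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear columns: {culprits}"
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - p
    sigma2 = float(resid @ resid) / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df_resid)
    return RegressionResult(names, beta, se, t, pvals, df_resid, n)


def _collinear_columns(X: np.ndarray, names: Sequence[str]) -> list[str]:
    """Columns that do not increase the rank of the preceding columns."""
    culprits = []
    rank = 0
    for j in range(X.shape[1]):
        new_rank = np.linalg.matrix_rank(X[:, : j + 1])
        if new_rank == rank:
            culprits.append(names[j])
        rank = new_rank
    return culprits


def fit_model(
    table: pd.DataFrame, dependent: str, regressors: Sequence[str]
) -> RegressionResult:
    """Fit ``dependent ~ 1 + regressors`` from a cohort table."""
    cols = [dependent, *regressors]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"cohort table is missing columns {missing}")
    if table[cols].isna().any().any():
        raise ValueError("cohort table has missing values in model columns")
    X = np.column_stack(
        [np.ones(len(table))] + [table[c].to_numpy(dtype=float) for c in regressors]
    )
    return fit_ols(
        table[dependent].to_numpy(dtype=float), X, ("intercept", *regressors)
    )


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation with a two-sided p-value via the t transform.

    ``t = r sqrt((n-2) / (1-r^2))`` with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance in input")
    r = float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p
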