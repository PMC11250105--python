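"""Differential abundance, covariate-adjusted regression, and FDR control.

All per-feature tests return a tidy table with the raw p-value and the
Benjamini-Hochberg adjusted q-value; the BH family is the set of features
tested together for one contrast or trait.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "bh_adjust",
    "differential_abundance",
    "covariate_adjusted_regression",
    "pairwise_correlation",
    "partial_correlation",
]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (p_(j) * m / j), capped at 1.  NaN entries are
    excluded from the family and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if np.any((p[ok] < 0) | (p[ok] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def differential_abundance(matrix: pd.DataFrame, groups, ref: str = "ND",
                           equal_var: bool = True) -> pd.DataFrame:
    """Per-feature two-sided t-test between two donor groups.

    ``matrix`` is features x donors on a log10 scale (post-normalization);
    log2 fold change is the group mean difference divided by log10(2).
    Constant features get p = 1 and a flag.  Significance is q < 0.05.
    """
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    alt = [l for l in labels if l != ref][0]
    X = matrix.to_numpy(dtype=float)
    a = X[:, groups == ref]
    b = X[:, groups == alt]
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("need >= 2 donors per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(b, a, axis=1, equal_var=equal_var)
    log2fc = (np.nanmean(b, axis=1) - np.nanmean(a, axis=1)) / np.log10(2.0)
    const = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0)
    p = np.where(const, 1.0, p)
    t = np.where(const, 0.0, t)
    out = pd.DataFrame({
        "feature": matrix.index, "model": "ttest", "log2fc": log2fc,
        "statistic": t, "p": p, "q": bh_adjust(p),
        "n": a.shape[1] + b.shape[1],
        "flag": np.where(const, "constant", ""),
    })
    out["significant"] = out["q"] < 0.05
    return out


def covariate_adjusted_regression(matrix: pd.DataFrame, trait,
                                  covariates: pd.DataFrame | None = None,
                                  ) -> pd.DataFrame:
    """Per-feature OLS of abundance on a trait, adjusting for covariates.

    Fits ``abundance ~ trait + covariates`` (e.g. T2D status coded 0/1) for
    every feature at once and reports the trait coefficient, its t-test
    p-value and the BH q across features.
    """
    y = matrix.to_numpy(dtype=float).T            # donors x features
    t = np.asarray(trait, dtype=float)
    n = t.size
    if y.shape[0] != n:
        raise ValueError("trait length must match donor count")
    cols = [np.ones(n), t]
    names = ["intercept", "trait"]
    if covariates is not None:
        for name in covariates.columns:
            cols.append(covariates[name].to_numpy(dtype=float))
            names.append(name)
    X = np.column_stack(cols)
    k = X.shape[1]
    if n <= k + 1:
        raise ValueError("need n > number of covariates + 2")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("collinear design matrix (trait vs covariates)")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y                      # k x features
    resid = y - X @ beta
    dof = n - k
    s2 = (resid ** 2).sum(axis=0) / dof
    se = np.sqrt(np.maximum(s2, 0.0) * XtX_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta[1] / se
    p = 2.0 * stats.t.sf(np.abs(tstat), dof)
    degenerate = se == 0
    p = np.where(degenerate, 1.0, p)
    out = pd.DataFrame({
        "feature": matrix.index, "model": "ols", "coefficient": beta[1],
        "se": se, "statistic": tstat, "p": p, "q": bh_adjust(p), "n": n,
        "covariates": ",".join(names[2:]),
        "flag": np.where(degenerate, "zero_variance", ""),
    })
    out["significant"] = out["q"] < 0.05
    return out


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(len(v))] + [Z[:, j] for j in range(Z.shape[1])])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Implemented by double residualization on the covariate set; the p-value
    uses a t distribution with n - 2 - |Z| degrees of freedom.  With an empty
    covariate set this is the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        Z = np.empty((x.size, 0))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != x.size:
            Z = Z.T
    nz = Z.shape[1]
    n = x.size
    if n < nz + 4 and nz > 0:
        raise ValueError("need n >= 4 + number of covariates")
    if n < 3:
        raise ValueError("need n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    if nz:
        sx, sy = np.std(x), np.std(y)
        x = _residualize(x, Z)
        y = _residualize(y, Z)
        # a variable fully explained by the covariates has a null residual;
        # its partial correlation with anything is 0 by convention
        if np.std(x) < 1e-10 * sx or np.std(y) < 1e-10 * sy:
            return 0.0, 1.0
    r = float(np.corrcoef(x, y)[0, 1])
    dof = n - 2 - nz
    r_ = min(max(r, -0.9999999999), 0.9999999999)
    tstat = r_ * np.sqrt(dof / (1.0 - r_ * r_))
    p = float(2.0 * stats.t.sf(abs(tstat), dof))
    return r, p


def pairwise_correlation(x, y, method: str = "pearson", covariates=None,
                         ) -> tuple[float, float]:
    """Pearson or partial Pearson correlation with p-value."""
    if method == "pearson":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 3:
            raise ValueError("need n >= 3")
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError("zero-variance input")
        res = stats.pearsonr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "partial":
        return partial_correlation(x, y, covariates)
    raise ValueError(f"unknown method {method!r}")
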