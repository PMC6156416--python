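"""Evolutionary rate matrices and correlations under lambda-Brownian motion.

For traits X (n species x p traits) evolving by Brownian motion on a tree
with covariance C(lambda), the evolutionary rate matrix is estimated as

    a_hat = (1' C^-1 1)^-1 1' C^-1 X          (phylogenetic means)
    R     = (X - 1 a_hat)' C(lambda)^-1 (X - 1 a_hat) / (n - 1)

and the evolutionary correlation r_ij = R_ij / sqrt(R_ii R_jj): the
Pearson correlation between evolutionary changes in the two traits. On a
star tree (lambda = 0 everywhere, equal depths) R reduces to the ordinary
sample covariance.

Lambda can be fixed or estimated per trait set by maximizing the joint
(matrix-normal) lambda-Brownian likelihood. The full correlation matrix
uses pairwise-complete species per pair (so it need not be positive
semi-definite — a warning is emitted when it is not), with two-sided
significance from t = r sqrt((n - 2) / (1 - r^2)) on n - 2 df and a
significance mask at a configurable alpha (default 0.1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_solve

from .errors import FitError
from .signal import _chol, _LOG2PI
from .traits import TraitTable
from .tree import Phylogeny, apply_lambda

__all__ = ["rate_matrix", "evolutionary_correlation", "correlation_matrix", "fit_lambda_joint"]


def rate_matrix(X, C, lam: float = 1.0):
    """Evolutionary rate (covariance) matrix of traits ``X`` given ``C``.

    ``X`` is n x p with complete cases; returns the p x p matrix R
    (divisor n - 1) on the lambda-transformed covariance.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if n <= 2:
        raise FitError(f"need more than 2 species, have {n}")
    if np.any(np.ptp(X, axis=0) == 0):
        raise FitError("zero-variance trait column")
    Cl = apply_lambda(np.asarray(C, dtype=float), lam)
    cf = _chol(Cl)
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    a = (one @ cho_solve(cf, X)) / (one @ Ci1)
    E = X - a
    R = E.T @ cho_solve(cf, E) / (n - 1)
    return R


def fit_lambda_joint(X, C, grid_size: int = 21, tol: float = 1e-6) -> float:
    """ML lambda for a multi-trait lambda-Brownian model.

    Maximizes the matrix-normal profile likelihood over lambda in [0, 1]
    with the per-trait means and the rate matrix profiled out analytically.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    C = np.asarray(C, dtype=float)

    def nll(lam):
        Cl = apply_lambda(C, lam)
        cf = _chol(Cl)
        one = np.ones(n)
        a = (one @ cho_solve(cf, X)) / (one @ cho_solve(cf, one))
        E = X - a
        S = E.T @ cho_solve(cf, E) / n  # ML divisor for the likelihood
        sign, logdetS = np.linalg.slogdet(S)
        if sign <= 0:
            return np.inf
        logdetC = 2.0 * np.sum(np.log(np.diag(cf[0])))
        ll = -0.5 * (n * p * _LOG2PI + n * logdetS + p * logdetC + n * p)
        return -ll

    grid = np.linspace(0.0, 1.0, grid_size)
    vals = np.array([nll(l) for l in grid])
    best = int(np.argmin(vals))
    lo, hi = grid[max(best - 1, 0)], grid[min(best + 1, grid_size - 1)]
    res = optimize.minimize_scalar(nll, bounds=(lo, hi), method="bounded",
                                   options={"xatol": tol})
    lam = float(res.x)
    if vals[best] < res.fun:
        lam = float(grid[best])
    return lam


def evolutionary_correlation(x, y, C, lam="ml"):
    """Evolutionary correlation of one trait pair.

    Returns (r, p, n, lambda_used); the p-value is a two-sided t test on
    n - 2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([x, y])
    n = len(x)
    if n < 4:
        raise FitError(f"need >= 4 pairwise-complete species, have {n}")
    lam_used = fit_lambda_joint(X, C) if lam == "ml" else float(lam)
    R = rate_matrix(X, C, lam_used)
    r = float(R[0, 1] / np.sqrt(R[0, 0] * R[1, 1]))
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p, n, lam_used


def correlation_matrix(
    table: TraitTable,
    tree: Phylogeny,
    columns=None,
    alpha: float = 0.1,
    lam="ml",
):
    """Pairwise-complete evolutionary correlation matrix with significance mask.

    Each pair of columns is estimated on the species measured for both and
    present on the tree. Returns ``(r, p, mask)`` DataFrames; cells with
    fewer than 4 complete pairs are NaN (not estimable) and unmasked.
    """
    columns = list(columns or table.columns)
    k = len(columns)
    r = pd.DataFrame(np.eye(k), index=columns, columns=columns)
    p = pd.DataFrame(np.zeros((k, k)), index=columns, columns=columns)
    nmat = pd.DataFrame(np.zeros((k, k), dtype=int), index=columns, columns=columns)
    tips = set(tree.tip_labels)
    for i in range(k):
        for j in range(i + 1, k):
            sub = table.df[[columns[i], columns[j]]].dropna()
            common = [t for t in tree.tip_labels if t in set(sub.index) and t in tips]
            nmat.iloc[i, j] = nmat.iloc[j, i] = len(common)
            if len(common) < 4:
                r.iloc[i, j] = r.iloc[j, i] = np.nan
                p.iloc[i, j] = p.iloc[j, i] = np.nan
                continue
            C = tree.vcv(common)
            sub = sub.loc[common]
            rij, pij, _, _ = evolutionary_correlation(
                sub[columns[i]], sub[columns[j]], C, lam=lam
            )
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
    mask = (p < alpha) & p.notna()
    np.fill_diagonal(mask.values, False)

    vals = r.to_numpy()
    if not np.isnan(vals).any():
        eig = np.linalg.eigvalsh((vals + vals.T) / 2.0)
        if eig.min() < -1e-8:
            warnings.warn(
                "pairwise-complete correlation matrix is not positive "
                "semi-definite (smallest eigenvalue %.3g)" % eig.min()
            )
    return r, p, mask
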