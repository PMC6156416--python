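"""Phylogenetic generalized least squares regression with residual lambda.

The model is y = X beta + e with phylogenetically correlated residuals,
e ~ N(0, sigma2 * C(lambda)); the GLS estimator is

    beta_hat = (X' V^-1 X)^-1 X' V^-1 y,      V = C(lambda),

with lambda estimated by maximizing the profile likelihood of the
residual model over [0, 1] (lambda = 0 reduces exactly to OLS). Standard
errors use sigma2_hat = RSS_gls / (n - m - 1) so per-coefficient t tests
have n - m - 1 df; the reported log-likelihood is the ML fit (divisor n).
The whole-model p-value is an F test of all non-intercept coefficients
against the intercept-only model, both evaluated at the full model's
fitted lambda.

Out-of-sample prediction follows the Garland-Ives GLS best linear
unbiased predictor: for a new species with design row x0 and covariance
vector v0 to the training species,

    yhat0 = x0' beta_hat + v0' V^-1 (y - X beta_hat)

with prediction variance

    sigma2 [ (c00 - v0' V^-1 v0) + u' (X' V^-1 X)^-1 u ],
    u = x0 - X' V^-1 v0,

which reduces to the familiar OLS leverage form when v0 = 0 and lambda = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin

from .errors import FitError
from .signal import _chol, _LOG2PI
from .traits import TraitTable
from .tree import Phylogeny, apply_lambda

__all__ = ["PglsFit", "gls_estimate", "fit_pgls", "PGLS"]


@dataclass
class PglsFit:
    """A fitted PGLS model."""

    beta: np.ndarray          #: coefficients, intercept first
    se: np.ndarray            #: standard errors of beta
    t_stat: np.ndarray        #: beta / se
    p_coef: np.ndarray        #: two-sided t-test p-values, n - m - 1 df
    lambda_resid: float       #: ML residual lambda
    sigma2_resid: float       #: residual rate, RSS_gls / (n - m - 1)
    loglik: float             #: ML log-likelihood of the residual model
    n: int                    #: species used
    model_p: float            #: F-test of all non-intercept coefficients
    names: list = field(default_factory=list)  #: coefficient names
    species: list = field(default_factory=list)


def _check_design(X: np.ndarray, names=None):
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        names = names or [f"x{j}" for j in range(p)]
        raise FitError(f"design matrix is rank deficient; check columns {names}")
    return n, p


def gls_estimate(X, y, C):
    """GLS solve of beta = (X'C^-1 X)^-1 X'C^-1 y with inference pieces.

    Returns a dict with beta, se, cov_beta, rss (GLS residual sum of
    squares), sigma2 (divisor n - p), loglik (ML, divisor n) and the
    Cholesky factor of C for reuse.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    C = np.asarray(C, dtype=float)
    n, p = _check_design(X)
    if n <= p:
        raise FitError(f"need n > m + 1 complete cases (n={n}, columns={p})")
    cf = _chol(C)
    CiX = cho_solve(cf, X)
    Ciy = cho_solve(cf, y)
    XtCiX = X.T @ CiX
    beta = np.linalg.solve(XtCiX, X.T @ Ciy)
    r = y - X @ beta
    rss = float(r @ cho_solve(cf, r))
    sigma2 = rss / (n - p)
    cov_beta = sigma2 * np.linalg.inv(XtCiX)
    se = np.sqrt(np.diag(cov_beta))
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    s2_ml = rss / n
    loglik = -0.5 * (n * _LOG2PI + n * np.log(s2_ml) + logdet + n)
    return {
        "beta": beta,
        "se": se,
        "cov_beta": cov_beta,
        "rss": rss,
        "sigma2": sigma2,
        "loglik": float(loglik),
        "chol": cf,
        "XtCiX": XtCiX,
    }


def _profile_ll(lam, X, y, C):
    return gls_estimate(X, y, apply_lambda(C, lam))["loglik"]


def _ml_lambda(X, y, C, grid_size=26, tol=1e-8):
    grid = np.linspace(0.0, 1.0, grid_size)
    lls = np.array([_profile_ll(l, X, y, C) for l in grid])
    best = int(np.argmax(lls))
    lo, hi = grid[max(best - 1, 0)], grid[min(best + 1, grid_size - 1)]
    res = optimize.minimize_scalar(
        lambda l: -_profile_ll(l, X, y, C), bounds=(lo, hi), method="bounded",
        options={"xatol": tol},
    )
    lam = float(res.x)
    ll = -float(res.fun)
    for lb, lv in ((grid[0], lls[0]), (grid[-1], lls[-1]), (grid[best], lls[best])):
        if lv > ll:
            lam, ll = float(lb), float(lv)
    return lam, ll


class PGLS(RegressorMixin, BaseEstimator):
    """Phylogenetic GLS regression estimator.

    Parameters
    ----------
    tree : Phylogeny
    lam : "ml" or float in [0, 1]
        Residual lambda; estimated jointly with beta by ML when "ml".
    add_intercept : bool
        Prepend an intercept column (default True).

    After :meth:`fit`: ``coef_`` (intercept first), ``se_``, ``t_``,
    ``pvalues_``, ``lambda_``, ``sigma2_``, ``loglik_``, ``model_pvalue_``,
    ``n_``, ``fit_`` (a :class:`PglsFit`).
    """

    def __init__(self, tree: Phylogeny | None = None, lam="ml", add_intercept: bool = True):
        self.tree = tree
        self.lam = lam
        self.add_intercept = add_intercept

    # -------------------------------------------------------------------- fit
    def fit(self, X, y, species=None, feature_names=None):
        """Fit on design ``X`` (n x m) and outcome ``y`` for ``species``.

        ``X`` may be a DataFrame (species index and column names inferred);
        ``species`` must otherwise list the tip labels row by row.
        """
        if self.tree is None:
            raise FitError("PGLS requires a tree")
        if isinstance(X, pd.DataFrame):
            species = species or list(X.index)
            feature_names = feature_names or list(X.columns)
            X = X.to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float)
        if species is None:
            species = self.tree.tip_labels
        species = list(species)
        if len(species) != X.shape[0] or len(y) != X.shape[0]:
            raise FitError("X, y and species must have matching lengths")
        names = list(feature_names or [f"x{j + 1}" for j in range(X.shape[1])])
        if self.add_intercept:
            X = np.column_stack([np.ones(X.shape[0]), X])
            names = ["intercept"] + names
        _check_design(X, names)

        C = self.tree.vcv(species)
        if self.lam == "ml":
            lam, _ = _ml_lambda(X, y, C)
        else:
            lam = float(self.lam)
            if not 0.0 <= lam <= 1.0:
                raise FitError(f"lambda must be in [0, 1], got {lam}")
        V = apply_lambda(C, lam)
        est = gls_estimate(X, y, V)
        n, p = X.shape
        df = n - p
        t = est["beta"] / est["se"]
        pvals = 2.0 * stats.t.sf(np.abs(t), df)

        # F test of the full model against intercept-only at the same lambda
        if self.add_intercept and p > 1:
            est0 = gls_estimate(X[:, :1], y, V)
            fstat = ((est0["rss"] - est["rss"]) / (p - 1)) / (est["rss"] / df)
            model_p = float(stats.f.sf(fstat, p - 1, df))
        else:
            model_p = float("nan")

        self.coef_ = est["beta"]
        self.se_ = est["se"]
        self.t_ = t
        self.pvalues_ = pvals
        self.lambda_ = lam
        self.sigma2_ = est["sigma2"]
        self.loglik_ = est["loglik"]
        self.model_pvalue_ = model_p
        self.n_ = n
        self.feature_names_ = names
        self.species_ = species
        self._X = X
        self._y = y
        self._V = V
        self._est = est
        self.fit_ = PglsFit(
            est["beta"], est["se"], t, pvals, lam, est["sigma2"], est["loglik"],
            n, model_p, names, species,
        )
        return self

    # ---------------------------------------------------------------- predict
    def predict(self, X, species=None, interval: bool = False, full_tree: Phylogeny | None = None):
        """Garland-Ives BLUP for new species on the tree.

        With ``interval=True`` returns a DataFrame with ``predicted``,
        ``var``, ``ci_low``, ``ci_high`` (95%, +/- 1.96 sd); otherwise the
        point predictions. ``full_tree`` defaults to the training tree and
        must contain both training and new species.
        """
        if isinstance(X, pd.DataFrame):
            species = species or list(X.index)
            X = X.to_numpy(dtype=float)
        X0 = np.asarray(X, dtype=float)
        if X0.ndim == 1:
            X0 = X0[:, None]
        if species is None:
            raise FitError("predict requires the species labels of the new rows")
        species = list(species)
        if self.add_intercept:
            X0 = np.column_stack([np.ones(X0.shape[0]), X0])
        tree = full_tree or self.tree
        # covariance between new and training species on the lambda scale
        both = self.species_ + species
        Call = tree.vcv(both)
        k = len(self.species_)
        V0 = self.lambda_ * Call[k:, :k]                 # cross-covariances
        c00 = np.diag(Call)[k:]                          # own depths (diagonal untouched)

        est = self._est
        cf = est["chol"]
        resid = self._y - self._X @ est["beta"]
        Cir = cho_solve(cf, resid)
        preds = X0 @ est["beta"] + V0 @ Cir
        if not interval:
            return preds
        XtCiXinv = np.linalg.inv(est["XtCiX"])
        out = []
        for i in range(X0.shape[0]):
            v0 = V0[i]
            Civ = cho_solve(cf, v0)
            u = X0[i] - self._X.T @ Civ
            var = est["sigma2"] * ((c00[i] - v0 @ Civ) + u @ XtCiXinv @ u)
            out.append(max(var, 0.0))
        var = np.asarray(out)
        half = 1.96 * np.sqrt(var)
        return pd.DataFrame(
            {"predicted": preds, "var": var, "ci_low": preds - half, "ci_high": preds + half},
            index=species,
        )


def fit_pgls(
    table: TraitTable,
    tree: Phylogeny,
    outcome: str,
    predictors,
    log_outcome: bool = False,
    lam="ml",
) -> PglsFit:
    """Fit a PGLS model of ``outcome`` on ``predictors`` from a trait table.

    Uses the species jointly non-missing for the outcome and every
    predictor that are also on the tree; optionally log-transforms the
    outcome first (natural log).
    """
    predictors = list(predictors)
    if log_outcome:
        table = table.transform(outcome, "log")
    cols = [outcome] + predictors
    sub = table.df[cols].dropna()
    common = [t for t in tree.tip_labels if t in set(sub.index)]
    m = len(predictors)
    if len(common) < m + 3:
        raise FitError(
            f"only {len(common)} complete cases on the tree for {outcome} ~ "
            f"{predictors}; need at least {m + 3}"
        )
    sub = sub.loc[common]
    model = PGLS(tree=tree, lam=lam).fit(
        sub[predictors], sub[outcome].to_numpy(), species=common
    )
    return model.fit_
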