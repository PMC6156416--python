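"""Maximum-likelihood estimation of Pagel's lambda and the Brownian rate.

Under lambda-corrected Brownian motion a trait vector ``x`` over the tips
of a tree is multivariate normal,

    x ~ N(mu * 1, sigma2 * C(lambda)),

where ``C`` is the phylogenetic covariance (shared root-to-MRCA branch
length) and ``C(lambda)`` scales its off-diagonals by lambda in [0, 1]:
lambda = 0 means trait variation independent of phylogeny (a star tree,
the OLS limit), lambda = 1 pure Brownian motion on the original tree.

For fixed lambda the mean and rate have closed-form ML solutions

    mu_hat     = (1' C^-1 1)^-1 1' C^-1 x
    sigma2_hat = (x - mu_hat 1)' C^-1 (x - mu_hat 1) / n        (ML, divisor n)

so lambda is found by maximizing the profile log-likelihood on [0, 1]
(coarse grid scan to locate the global basin, then bounded Brent
refinement, tol 1e-8). Significance of phylogenetic signal is a likelihood
ratio test of lambda = 0 against chi-square with 1 df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator

from .errors import FitError
from .tree import Phylogeny, apply_lambda

__all__ = ["SignalFit", "bm_loglik", "fit_signal", "PhylogeneticSignal"]

_LOG2PI = float(np.log(2.0 * np.pi))


def _chol(C: np.ndarray):
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        raise FitError(
            "singular phylogenetic covariance; check for duplicate tips at "
            "zero phylogenetic distance"
        ) from None


def bm_loglik(values, C, lam: float, sigma2: float, mu: float) -> float:
    """Log-likelihood of a trait vector under lambda-corrected Brownian motion.

    The multivariate normal log-density of ``values`` with mean ``mu * 1``
    and covariance ``sigma2 * C(lambda)``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise FitError("need at least 2 tip values")
    if sigma2 <= 0:
        raise FitError("sigma2 must be positive")
    Cl = apply_lambda(np.asarray(C, dtype=float), lam)
    cf = _chol(Cl)
    r = x - mu
    quad = r @ cho_solve(cf, r) / sigma2
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0]))) + n * np.log(sigma2)
    return float(-0.5 * (n * _LOG2PI + logdet + quad))


def _profile(lam: float, C: np.ndarray, x: np.ndarray):
    """Profile log-likelihood at lambda, with mu and sigma2 maximized out."""
    n = x.size
    Cl = apply_lambda(C, lam)
    cf = _chol(Cl)
    one = np.ones(n)
    Ci1 = cho_solve(cf, one)
    mu = float((one @ cho_solve(cf, x)) / (one @ Ci1))
    r = x - mu
    s2 = float(r @ cho_solve(cf, r)) / n
    if s2 <= 0:
        raise FitError("degenerate fit: trait vector is constant")
    logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
    ll = -0.5 * (n * _LOG2PI + n * np.log(s2) + logdet + n)
    return float(ll), mu, s2


@dataclass
class SignalFit:
    """ML fit of the lambda-Brownian model for one trait on one tree."""

    lambda_hat: float   #: Pagel's lambda in [0, 1]
    sigma2_hat: float   #: Brownian rate, trait-units^2 per unit branch length
    root_state: float   #: GLS estimate of the root (phylogenetic mean)
    loglik: float       #: maximized log-likelihood
    n: int              #: number of species used
    lrt_p: float        #: p-value of the lambda = 0 likelihood ratio test
    loglik0: float      #: log-likelihood at lambda = 0


def fit_signal(
    values,
    tree: Phylogeny | None = None,
    *,
    C: np.ndarray | None = None,
    grid_size: int = 26,
    tol: float = 1e-8,
) -> SignalFit:
    """Fit Pagel's lambda, sigma^2 and the root state by maximum likelihood.

    ``values`` may be a pandas Series indexed by species (aligned against
    ``tree``) or a plain vector ordered like ``C``/the tree's tips. Either
    ``tree`` or a precomputed covariance ``C`` must be given.
    """
    if hasattr(values, "index") and tree is not None:
        labels = list(values.index)
        x = np.asarray(values, dtype=float)
        if C is None:
            C = tree.vcv(labels)
    else:
        x = np.asarray(values, dtype=float)
        if C is None:
            if tree is None:
                raise FitError("provide a tree or a covariance matrix")
            C = tree.vcv()
    C = np.asarray(C, dtype=float)
    n = x.size
    if n < 2 or C.shape != (n, n):
        raise FitError(f"shape mismatch: {n} values vs covariance {C.shape}")
    if n < 4:
        warnings.warn(f"only n={n} species; lambda estimate will be unstable")
    if np.ptp(x) == 0:
        raise FitError("degenerate fit: trait vector is constant")

    grid = np.linspace(0.0, 1.0, grid_size)
    lls = np.array([_profile(l, C, x)[0] for l in grid])
    best = int(np.argmax(lls))

    # warn on near-tied local optima (within 2 log-likelihood units)
    interior = np.r_[False, (lls[1:-1] >= lls[:-2]) & (lls[1:-1] >= lls[2:]), False]
    interior[0] = lls[0] >= lls[1]
    interior[-1] = lls[-1] >= lls[-2]
    locs = np.flatnonzero(interior)
    if len(locs) > 1:
        top2 = np.sort(lls[locs])[-2:]
        if top2[1] - top2[0] < 2.0:
            warnings.warn(
                "lambda profile likelihood has two local optima within 2 "
                "log-likelihood units; reporting the global maximum"
            )

    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid_size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda l: -_profile(l, C, x)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": tol},
        )
        lam_hat = float(res.x)
    else:
        lam_hat = float(grid[best])
    ll_hat, mu_hat, s2_hat = _profile(lam_hat, C, x)
    # the bounded optimizer never evaluates the exact endpoints; keep the
    # better of the refined point and the grid boundaries
    for lam_b, ll_b in ((grid[0], lls[0]), (grid[-1], lls[-1]), (grid[best], lls[best])):
        if ll_b > ll_hat:
            lam_hat = float(lam_b)
            ll_hat, mu_hat, s2_hat = _profile(lam_hat, C, x)

    ll0 = float(lls[0])
    lrt = max(0.0, 2.0 * (ll_hat - ll0))
    p = float(stats.chi2.sf(lrt, df=1))
    return SignalFit(lam_hat, s2_hat, mu_hat, ll_hat, n, p, ll0)


class PhylogeneticSignal(BaseEstimator):
    """Estimator interface over :func:`fit_signal`.

    Parameters
    ----------
    tree : Phylogeny
        Rooted, time-calibrated tree whose tips cover the species.
    lam : "ml" or float in [0, 1]
        Estimate lambda by ML (default) or fix it.
    grid_size : int
        Points of the coarse lambda scan preceding Brent refinement.

    Attributes (after :meth:`fit`)
    ------------------------------
    lambda_, sigma2_, root_state_, loglik_, lrt_pvalue_, n_
    """

    def __init__(self, tree: Phylogeny | None = None, lam="ml", grid_size: int = 26):
        self.tree = tree
        self.lam = lam
        self.grid_size = grid_size

    def fit(self, values, y=None):
        """Fit on a species-indexed Series (or vector in tree tip order)."""
        if self.tree is None:
            raise FitError("PhylogeneticSignal requires a tree")
        if self.lam == "ml":
            fit = fit_signal(values, self.tree, grid_size=self.grid_size)
        else:
            lam = float(self.lam)
            if hasattr(values, "index"):
                C = self.tree.vcv(list(values.index))
            else:
                C = self.tree.vcv()
            x = np.asarray(values, dtype=float)
            ll, mu, s2 = _profile(lam, C, x)
            ll0 = _profile(0.0, C, x)[0]
            lrt = max(0.0, 2.0 * (ll - ll0))
            fit = SignalFit(lam, s2, mu, ll, x.size, float(stats.chi2.sf(lrt, 1)), ll0)
        self.lambda_ = fit.lambda_hat
        self.sigma2_ = fit.sigma2_hat
        self.root_state_ = fit.root_state
        self.loglik_ = fit.loglik
        self.lrt_pvalue_ = fit.lrt_p
        self.n_ = fit.n
        self.fit_ = fit
        return self
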