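"""Simulators for trees and lambda-Brownian traits.

These generators provide every fixture the test-suite and examples use —
nothing is downloaded. They emulate the statistical structure the
comparative methods assume: an ultrametric (time-calibrated) phylogeny,
traits drawn from multivariate normal distributions with covariance
sigma2 * C(lambda), optional between-trait rate correlations, regression
data with phylogenetically correlated residuals, and partial measurement
(a random fraction of tips retains values, missing completely at random).

Trees come from a pure-birth (Yule) process: with k extant lineages the
waiting time to the next speciation is Exponential(k * birth_rate), the
splitting lineage is uniform, and after the n-th lineage appears one more
exponential interval is appended so the tree ends between events. All
randomness flows through one ``numpy.random.Generator`` seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .traits import TraitTable
from .tree import Phylogeny

__all__ = [
    "SimConfig",
    "simulate_yule_tree",
    "simulate_bm_traits",
    "simulate_pgls_data",
]


@dataclass
class SimConfig:
    """Bundle of simulation settings (all generators also take kwargs)."""

    n_tips: int = 100
    birth_rate: float = 1.0
    lambda_true: float = 1.0
    sigma2_true: float = 1.0
    root_state: float = 0.0
    n_traits: int = 1
    trait_corr: np.ndarray | None = None  #: between-trait rate correlation
    betas: np.ndarray | None = None       #: regression coefficients, intercept first
    measured_fraction: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.n_tips < 3:
            raise DataError("n_tips must be >= 3")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise DataError("lambda_true must be in [0, 1]")
        if not 0.0 < self.measured_fraction <= 1.0:
            raise DataError("measured_fraction must be in (0, 1]")
        if self.trait_corr is not None:
            R = np.asarray(self.trait_corr, dtype=float)
            if np.linalg.eigvalsh(R).min() <= 0:
                raise DataError("trait correlation matrix must be positive definite")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0, seed=None) -> Phylogeny:
    """Pure-birth ultrametric tree with ``n_tips`` extant species.

    Deterministic under a fixed seed. Tips are labeled ``t1..tn`` in
    preorder.
    """
    if n_tips < 3:
        raise DataError("n_tips must be >= 3")
    rng = _rng(seed)
    # event-time bookkeeping: each extant lineage has a birth time; at a
    # speciation the chosen lineage becomes an internal node with two kids
    birth_time = [0.0]
    children: dict[int, list[int]] = {}
    node_birth = {0: 0.0}
    extant = [0]
    next_id = 1
    t = 0.0
    k = 1
    while k < n_tips:
        t += rng.exponential(1.0 / (birth_rate * k))
        idx = rng.integers(0, k)
        parent = extant[idx]
        a, b = next_id, next_id + 1
        next_id += 2
        children[parent] = [a, b]
        node_birth[a] = node_birth[b] = t
        extant[idx] = a
        extant.append(b)
        k += 1
    t += rng.exponential(1.0 / (birth_rate * k))
    total = t

    # flatten to preorder arrays
    parents, lengths, labels = [-1], [0.0], [None]
    ids = {0: 0}
    stack = [c for c in reversed(children.get(0, []))]
    order_parent = {c: 0 for c in children.get(0, [])}
    tip_counter = 0
    while stack:
        old = stack.pop()
        nid = len(parents)
        ids[old] = nid
        p_old = order_parent[old]
        parents.append(ids[p_old])
        kids = children.get(old)
        if kids:
            end = min(node_birth[kids[0]], total)
            lengths.append(end - node_birth[old])
            labels.append(None)
            for c in reversed(kids):
                order_parent[c] = old
            stack.extend(reversed(kids))
        else:
            tip_counter += 1
            lengths.append(total - node_birth[old])
            labels.append(f"t{tip_counter}")
    return Phylogeny(parents, lengths, labels)


def simulate_bm_traits(
    tree: Phylogeny,
    n_traits: int = 1,
    lam: float = 1.0,
    sigma2: float = 1.0,
    root_state: float = 0.0,
    trait_corr=None,
    measured_fraction: float = 1.0,
    seed=None,
    prefix: str = "trait",
) -> TraitTable:
    """Draw lambda-Brownian traits on a tree.

    Tip values are multivariate normal with mean ``root_state`` and
    covariance ``sigma2 * C(lam)``; with ``trait_corr`` given, the joint
    covariance is the Kronecker product ``(sigma2 * trait_corr) (x) C(lam)``
    so evolutionary changes in different traits correlate. A fraction
    ``1 - measured_fraction`` of tips (rounded) is masked to missing,
    independently per trait.
    """
    if not 0.0 < measured_fraction <= 1.0:
        raise DataError("measured_fraction must be in (0, 1]")
    rng = _rng(seed)
    n = tree.n_tips
    C = tree.vcv(lam=lam)
    if sigma2 == 0.0:
        X = np.full((n, n_traits), float(root_state))
    else:
        Lc = np.linalg.cholesky(sigma2 * C + 1e-12 * np.eye(n))
        Z = rng.standard_normal((n, n_traits))
        X = root_state + Lc @ Z
        if trait_corr is not None:
            R = np.asarray(trait_corr, dtype=float)
            if R.shape != (n_traits, n_traits):
                raise DataError("trait_corr shape must be (n_traits, n_traits)")
            X = root_state + (X - root_state) @ np.linalg.cholesky(R).T
    df = pd.DataFrame(
        X, index=tree.tip_labels, columns=[f"{prefix}{j + 1}" for j in range(n_traits)]
    )
    n_mask = round((1.0 - measured_fraction) * n)
    for col in df.columns:
        if n_mask:
            drop = rng.choice(n, size=n_mask, replace=False)
            df.iloc[drop, df.columns.get_loc(col)] = np.nan
    return TraitTable(df)


def simulate_pgls_data(
    tree: Phylogeny,
    betas,
    lam: float = 1.0,
    sigma2: float = 1.0,
    predictor_means=None,
    predictor_sds=None,
    seed=None,
    outcome: str = "outcome",
) -> TraitTable:
    """Regression testbed: outcome = X beta + lambda-Brownian residual.

    ``betas`` is (intercept, b1, ..., bm); predictors are drawn i.i.d.
    normal (defaults: mean 0, sd 1) and named ``pred1..predm``. The truths
    are recorded on the returned table as ``.sim_truth``.
    """
    rng = _rng(seed)
    betas = np.asarray(betas, dtype=float)
    m = len(betas) - 1
    n = tree.n_tips
    means = np.asarray(predictor_means if predictor_means is not None else np.zeros(m), float)
    sds = np.asarray(predictor_sds if predictor_sds is not None else np.ones(m), float)
    P = means + sds * rng.standard_normal((n, m))
    if sigma2 == 0.0:
        resid = np.zeros(n)
    else:
        C = tree.vcv(lam=lam)
        resid = np.linalg.cholesky(sigma2 * C + 1e-12 * np.eye(n)) @ rng.standard_normal(n)
    y = betas[0] + P @ betas[1:] + resid
    df = pd.DataFrame(P, index=tree.tip_labels,
                      columns=[f"pred{j + 1}" for j in range(m)])
    df[outcome] = y
    table = TraitTable(df)
    table.sim_truth = {"betas": betas, "lambda": lam, "sigma2": sigma2}
    return table


def example_tree() -> Phylogeny:
    """The bundled synthetic 84-tip Yule example tree.

    Generated once with ``simulate_yule_tree(84, birth_rate=1.0, seed=84)``
    and shipped as a Newick file; handy for examples and smoke tests.
    """
    from importlib.resources import files

    text = files("phylopred.data").joinpath("yule84_synthetic.nwk").read_text()
    from .tree import parse_newick

    return parse_newick(text)


def simulate_from_config(config: SimConfig):
    """Convenience: tree plus traits from one :class:`SimConfig`."""
    rng = _rng(config.seed)
    tree = simulate_yule_tree(config.n_tips, config.birth_rate, seed=rng)
    if config.betas is not None:
        table = simulate_pgls_data(tree, config.betas, config.lambda_true,
                                   config.sigma2_true, seed=rng)
    else:
        table = simulate_bm_traits(
            tree, config.n_traits, config.lambda_true, config.sigma2_true,
            config.root_state, config.trait_corr, config.measured_fraction, seed=rng,
        )
    return tree, table
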