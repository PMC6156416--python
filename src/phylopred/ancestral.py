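"""Ancestral state reconstruction and phylogenetic imputation of tips.

Reconstruction: under Brownian motion the joint density of all node
values factorizes over branches, so the ML states of the internal nodes
given the tip values minimize

    sum over branches (x_child - x_parent)^2 / branch_length,

a weighted graph-Laplacian linear system (the joint-GLS solution; for a
Gaussian model the joint mode equals the per-node conditional mean, i.e.
the classical GLS/`fastAnc`-style estimates). Branch lengths of zero are
clamped to a tiny fraction of tree depth.

Imputation of an unmeasured tip follows the lambda-Brownian prediction
procedure:

1. fit Pagel's lambda and sigma^2 to the measured species;
2. rescale the full tree's branch lengths by lambda-hat;
3. prune to the measured species and reconstruct ancestral states;
4. locate the attachment point: the MRCA of the unmeasured species and
   its closest measured relative, which lies on a branch of the pruned
   tree between the next deeper and the next more recent node connecting
   measured species (the latter may be a measured tip);
5. predict the branch-length-weighted mean of the two endpoint states
   (linear interpolation at the attachment depth — the Brownian-bridge
   conditional expectation), with variance t * sigma^2 where t is the
   path length from the attachment point to the unmeasured tip on the
   rescaled tree, and 95% interval +/- 1.96 * sqrt(t * sigma^2).

Because no drift is assumed, unmeasured sister species at the same
distance from their measured relatives receive identical predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import spsolve
from sklearn.base import BaseEstimator

from .errors import FitError, TreeError
from .signal import SignalFit, fit_signal, _profile
from .tree import Phylogeny

__all__ = [
    "AncestralStates",
    "TipPrediction",
    "reconstruct_ancestral",
    "PhylogeneticImputer",
    "predict_tip",
    "predict_all",
    "rank_nutrient_rich",
]

Z95 = 1.96  #: normal quantile used for the 95% prediction interval


@dataclass
class AncestralStates:
    """ML Brownian states for every node of a (lambda-rescaled) tree."""

    tree: Phylogeny
    states: np.ndarray  #: per node id; tips carry their observed values

    def state_of(self, node: int) -> float:
        return float(self.states[node])


def reconstruct_ancestral(values, tree: Phylogeny) -> AncestralStates:
    """ML ancestral states under Brownian motion (all tips measured).

    ``values`` is a Series indexed by tip label or a vector in the tree's
    preorder tip order. The rate sigma^2 cancels and is not needed.
    """
    if hasattr(values, "index"):
        x = np.asarray(values.reindex(tree.tip_labels), dtype=float)
    else:
        x = np.asarray(values, dtype=float)
    if x.size != tree.n_tips or np.any(~np.isfinite(x)):
        raise FitError("reconstruction needs one finite value per tip")
    if tree.n_tips < 2:
        raise FitError("need at least 2 tips")

    n = tree.n_nodes
    states = np.zeros(n)
    tipmask = np.zeros(n, dtype=bool)
    tipmask[tree.tip_ids] = True
    states[tree.tip_ids] = x
    internal = np.flatnonzero(~tipmask)
    if internal.size == 0:
        return AncestralStates(tree, states)

    eps = 1e-10 * max(tree.depths.max(), 1.0)
    w = 1.0 / np.maximum(tree.lengths, eps)  # edge weight above each node
    pos = {int(v): i for i, v in enumerate(internal)}

    rows, cols, vals = [], [], []
    rhs = np.zeros(internal.size)
    diag = np.zeros(internal.size)
    for child in range(1, n):
        p = tree.parent[child]
        wi = w[child]
        if not tipmask[child]:
            diag[pos[child]] += wi
        if not tipmask[p]:
            diag[pos[p]] += wi
        if tipmask[child]:
            rhs[pos[p]] += wi * states[child]
        elif tipmask[p]:  # cannot happen (tips are leaves) but keep symmetric
            rhs[pos[child]] += wi * states[p]
        else:
            rows.append(pos[p]); cols.append(pos[child]); vals.append(-wi)
            rows.append(pos[child]); cols.append(pos[p]); vals.append(-wi)
    rows.extend(range(internal.size))
    cols.extend(range(internal.size))
    vals.extend(diag)
    L = csr_matrix((vals, (rows, cols)), shape=(internal.size, internal.size))
    states[internal] = spsolve(L, rhs) if internal.size > 1 else rhs / diag
    return AncestralStates(tree, states)


@dataclass
class TipPrediction:
    """Imputed value and 95% prediction interval for one unmeasured tip."""

    species: str
    predicted: float   #: point prediction on the model scale
    t: float           #: branch length (time) from attachment point to tip
    var: float         #: prediction variance, t * sigma2
    ci_low: float
    ci_high: float
    anchor: str        #: description of the anchoring branch/node
    n_measured: int


class PhylogeneticImputer(BaseEstimator):
    """Impute unmeasured tips of a phylogeny from measured relatives.

    Parameters
    ----------
    tree : Phylogeny
        Full tree containing measured and unmeasured species (ultrametric
        unless ``lam`` is fixed at 1).
    lam : "ml" or float in [0, 1]
        Pagel's lambda for the branch rescaling; ML-estimated from the
        measured species by default.
    t_mode : "path" or "pendant"
        Interval variance uses t = attachment-to-tip path length on the
        rescaled tree (default) or the pendant branch only.

    After :meth:`fit`: ``lambda_``, ``sigma2_``, ``mu_`` (root/GLS mean),
    ``loglik_``, ``n_``, ``signal_fit_``, ``states_`` (AncestralStates on
    the rescaled pruned tree).
    """

    def __init__(self, tree: Phylogeny | None = None, lam="ml", t_mode: str = "path"):
        self.tree = tree
        self.lam = lam
        self.t_mode = t_mode

    # -------------------------------------------------------------------- fit
    def fit(self, values, y=None):
        """Fit from a Series of measured values indexed by species."""
        if self.tree is None:
            raise FitError("PhylogeneticImputer requires a tree")
        if self.t_mode not in ("path", "pendant"):
            raise FitError(f"t_mode must be 'path' or 'pendant', got {self.t_mode!r}")
        values = pd.Series(values).dropna()
        measured = [t for t in self.tree.tip_labels if t in set(values.index)]
        if len(measured) < 2:
            raise FitError("need at least 2 measured species on the tree")
        vals = values.loc[measured]

        C = self.tree.vcv(measured)
        if self.lam == "ml":
            sf = fit_signal(vals, self.tree, C=C)
        else:
            lam = float(self.lam)
            if not 0.0 <= lam <= 1.0:
                raise TreeError(f"lambda must be in [0, 1], got {lam}")
            x = vals.to_numpy(dtype=float)
            ll, mu, s2 = _profile(lam, C, x)
            ll0 = _profile(0.0, C, x)[0]
            sf = SignalFit(lam, s2, mu, ll, x.size, float("nan"), ll0)

        rescaled = self.tree.rescale_lambda(sf.lambda_hat)
        pruned, old_of = rescaled.prune_with_map(measured)
        anc = reconstruct_ancestral(vals, pruned)

        self.signal_fit_ = sf
        self.lambda_ = sf.lambda_hat
        self.sigma2_ = sf.sigma2_hat
        self.mu_ = sf.root_state
        self.loglik_ = sf.loglik
        self.n_ = sf.n
        self.measured_ = measured
        self.values_ = vals
        self.rescaled_ = rescaled
        self.pruned_ = pruned
        self.states_ = anc
        self._old_of = old_of  # pruned node id -> full-tree node id

        # per full-tree node: number of measured tip descendants and one
        # representative measured tip (for mapping onto the pruned tree)
        full = self.tree
        nn = full.n_nodes
        mcount = np.zeros(nn, dtype=np.intp)
        rep = np.full(nn, -1, dtype=np.intp)
        mset = {full.node_of(l) for l in measured}
        for i in range(nn - 1, -1, -1):
            if not full.children[i]:
                if i in mset:
                    mcount[i] = 1
                    rep[i] = i
            else:
                for c in full.children[i]:
                    mcount[i] += mcount[c]
                    if rep[i] == -1 and rep[c] != -1:
                        rep[i] = rep[c]
        self._mcount = mcount
        self._rep = rep
        # pruned ancestors (tip upward) per measured tip label
        self._pruned_node = {pruned.labels[i]: int(i) for i in pruned.tip_ids}
        return self

    # ---------------------------------------------------------------- helpers
    def _predict_one(self, label: str) -> TipPrediction:
        full, pruned = self.tree, self.pruned_
        u = full.node_of(label)
        if self._mcount[u]:
            raise FitError(f"species {label!r} is measured; nothing to impute")
        # attachment node A: MRCA of u and its closest measured relative
        a = full.parent[u]
        while a != -1 and self._mcount[a] == 0:
            a = full.parent[a]
        depth_u = self.rescaled_.depths[u]
        if a == -1:  # no measured relatives at all (cannot happen if n_ >= 1)
            raise FitError("no measured relatives on the tree")
        d_a = float(self.rescaled_.depths[a])

        # image of A in the pruned tree: walk from a measured representative
        # tip upward; B is the last pruned ancestor still inside A's subtree
        m1 = int(self._rep[a])
        b = self._pruned_node[full.labels[m1]]
        node = b
        while node != -1 and full.is_ancestor(a, int(self._old_of[node])):
            b = node
            node = int(pruned.parent[node]) if node != 0 else -1
        d_b = float(pruned.depths[b])
        st = self.states_.states

        if d_a >= d_b - 1e-12 * max(d_b, 1.0):
            pred = float(st[b])
            anchor = f"node:{self._describe(b)}"
        elif b == 0:
            # attachment deeper than any node connecting measured species
            pred = float(st[0])
            anchor = "root"
        else:
            p = int(pruned.parent[b])
            d_p = float(pruned.depths[p])
            if d_a <= d_p:  # numerical guard; A should lie on branch (p, b)
                pred = float(st[p])
                anchor = f"node:{self._describe(p)}"
            else:
                wgt = (d_a - d_p) / (d_b - d_p)
                pred = float((1.0 - wgt) * st[p] + wgt * st[b])
                anchor = f"branch:{self._describe(p)}->{self._describe(b)}"

        if self.t_mode == "pendant":
            t = float(self.rescaled_.lengths[u])
        else:
            t = float(depth_u - d_a)
        t = max(t, 0.0)
        var = t * self.sigma2_
        half = Z95 * np.sqrt(var)
        return TipPrediction(label, pred, t, var, pred - half, pred + half,
                             anchor, len(self.measured_))

    def _describe(self, pruned_node: int) -> str:
        lab = self.pruned_.labels[pruned_node]
        return lab if lab is not None else f"mrca@{self.pruned_.depths[pruned_node]:.4g}"

    # ---------------------------------------------------------------- predict
    def predict(self, species=None) -> pd.DataFrame:
        """Predict the listed species (default: every unmeasured tip).

        Returns a DataFrame indexed by species with columns ``predicted``,
        ``t``, ``var``, ``ci_low``, ``ci_high``, ``anchor``, ``n_measured``.
        """
        if not hasattr(self, "states_"):
            raise FitError("call fit() before predict()")
        if species is None:
            mset = set(self.measured_)
            species = [t for t in self.tree.tip_labels if t not in mset]
        preds = [self._predict_one(s) for s in species]
        return pd.DataFrame(
            {
                "predicted": [p.predicted for p in preds],
                "t": [p.t for p in preds],
                "var": [p.var for p in preds],
                "ci_low": [p.ci_low for p in preds],
                "ci_high": [p.ci_high for p in preds],
                "anchor": [p.anchor for p in preds],
                "n_measured": [p.n_measured for p in preds],
            },
            index=pd.Index([p.species for p in preds], name="species"),
        )


def predict_tip(label: str, tree: Phylogeny, values, lam="ml", t_mode="path") -> TipPrediction:
    """Impute one unmeasured tip from measured relatives (convenience)."""
    imp = PhylogeneticImputer(tree=tree, lam=lam, t_mode=t_mode).fit(values)
    return imp._predict_one(label)


def predict_all(tree: Phylogeny, table, column: str, lam="ml", t_mode="path") -> pd.DataFrame:
    """Impute every unmeasured tip of ``tree`` for one trait column."""
    values = table.column(column).dropna() if hasattr(table, "column") else pd.Series(table).dropna()
    imp = PhylogeneticImputer(tree=tree, lam=lam, t_mode=t_mode).fit(values)
    return imp.predict()


def rank_nutrient_rich(measured: pd.Series, predicted: pd.Series, k: int, family_map) -> pd.DataFrame:
    """Family summary of "nutrient-rich" species (top-k rule).

    Each species gets a single value — its measured value when available,
    otherwise its prediction — and is called rich if that value ranks
    within the ``k`` largest across all species. Returns one row per
    family (via ``family_map``: species -> family) with columns
    ``n_total`` (species with a value), ``n_measured`` and ``n_rich``,
    sorted by richness.
    """
    measured = pd.Series(measured).dropna()
    predicted = pd.Series(predicted).dropna()
    combined = predicted.copy()
    combined.loc[measured.index.intersection(combined.index)] = measured
    extra = measured.index.difference(combined.index)
    combined = pd.concat([combined, measured.loc[extra]])
    top = set(combined.sort_values(ascending=False, kind="stable").index[: int(k)])
    mset = set(measured.index)
    fam = pd.Series({s: family_map.get(s, "unknown") for s in combined.index})
    out = []
    for family, members in fam.groupby(fam).groups.items():
        members = list(members)
        out.append(
            {
                "family": family,
                "n_total": len(members),
                "n_measured": sum(1 for s in members if s in mset),
                "n_rich": sum(1 for s in members if s in top),
            }
        )
    df = pd.DataFrame(out).set_index("family")
    return df.sort_values(["n_rich", "n_total"], ascending=False)
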