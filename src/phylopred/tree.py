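"""Rooted, time-calibrated phylogenies and Brownian-motion covariance.

The :class:`Phylogeny` container stores a rooted tree in preorder arrays
(parent pointers, branch lengths, tip labels) and provides the covariance
machinery the comparative methods in this package are built on:

* the phylogenetic variance-covariance matrix ``C`` with
  ``C[i, j] = depth of the most recent common ancestor of tips i and j``
  and ``C[i, i] = root-to-tip depth`` (:meth:`Phylogeny.vcv`);
* Pagel's lambda transforms, either directly on the covariance
  (:func:`apply_lambda`: off-diagonals scaled by lambda, diagonal kept) or
  as a branch-length rescaling of an ultrametric tree
  (:meth:`Phylogeny.rescale_lambda`: internal branches multiplied by
  lambda, pendant branches stretched so every tip keeps its depth) — the
  two coincide on ultrametric trees;
* pruning to a tip subset with degree-2 nodes collapsed, MRCA lookup and
  patristic path lengths.

Newick reading and writing is delegated to dendropy; everything else is
computed here. Tip labels are matched after normalizing spaces to
underscores (case-sensitive otherwise). Branch lengths of exactly zero are
permitted (soft polytomies); negative or missing lengths are rejected.
"""

from __future__ import annotations

import numpy as np

from .errors import NewickParseError, TreeError

__all__ = [
    "Phylogeny",
    "parse_newick",
    "write_newick",
    "apply_lambda",
    "normalize_label",
]

#: relative tolerance on tip depths for the ultrametricity check
ULTRAMETRIC_RTOL = 1e-6


def normalize_label(label: str) -> str:
    """Normalize a tip label: strip quotes/whitespace, spaces -> underscores."""
    s = str(label).strip().strip("'\"")
    return s.replace(" ", "_")


class Phylogeny:
    """A rooted tree stored as preorder arrays.

    Node 0 is the root; ``parent[i] < i`` for every non-root node, so each
    subtree occupies a contiguous block of node ids. ``lengths[i]`` is the
    length of the branch *above* node ``i`` (0 for the root).

    Parameters
    ----------
    parent : array of int
        Parent node id per node, -1 for the root (node 0).
    lengths : array of float
        Branch length above each node; entry 0 is ignored.
    labels : sequence of str or None
        Tip label per node (None for internal nodes).
    """

    def __init__(self, parent, lengths, labels):
        self.parent = np.asarray(parent, dtype=np.intp)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = len(self.parent)
        if n == 0 or self.parent[0] != -1 or np.any(self.parent[1:] >= np.arange(1, n)):
            raise TreeError("nodes must be in preorder with node 0 as the unique root")
        if np.any(self.lengths[1:] < 0):
            bad = int(np.argmin(self.lengths[1:])) + 1
            raise NewickParseError(
                f"negative branch length {self.lengths[bad]} above node {bad}"
            )
        if np.any(~np.isfinite(self.lengths[1:])):
            raise NewickParseError("missing or non-finite branch length")
        self.lengths = self.lengths.copy()
        self.lengths[0] = 0.0

        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)

        self.tip_ids = np.array(
            [i for i in range(n) if not self.children[i]], dtype=np.intp
        )
        self.tip_labels = []
        self._label_to_node: dict[str, int] = {}
        for pos, i in enumerate(self.tip_ids):
            if self.labels[i] is None:
                raise NewickParseError(f"unlabeled tip node {i}")
            lab = normalize_label(self.labels[i])
            if lab in self._label_to_node:
                raise NewickParseError(f"duplicate tip label {lab!r}")
            self.labels[i] = lab
            self._label_to_node[lab] = i
            self.tip_labels.append(lab)
        # tip position in preorder tip ordering, per node id
        self._tip_pos = {int(i): p for p, i in enumerate(self.tip_ids)}

        # depths and subtree extents
        self.depths = np.zeros(n)
        for i in range(1, n):
            self.depths[i] = self.depths[self.parent[i]] + self.lengths[i]
        self.subtree_end = np.arange(1, n + 1, dtype=np.intp)
        for i in range(n - 1, 0, -1):
            p = self.parent[i]
            if self.subtree_end[i] > self.subtree_end[p]:
                self.subtree_end[p] = self.subtree_end[i]
        # contiguous tip-position range [lo, hi) of each node's subtree
        self._tip_lo = np.zeros(n, dtype=np.intp)
        self._tip_hi = np.zeros(n, dtype=np.intp)
        pos = np.searchsorted(self.tip_ids, np.arange(n))
        for i in range(n):
            self._tip_lo[i] = pos[i]
            self._tip_hi[i] = np.searchsorted(self.tip_ids, self.subtree_end[i] - 1, "right")
        self._vcv_cache: np.ndarray | None = None

    # ------------------------------------------------------------------ basic
    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_tips(self) -> int:
        return len(self.tip_ids)

    def node_of(self, label: str) -> int:
        """Node id of a tip label (after normalization)."""
        lab = normalize_label(label)
        try:
            return self._label_to_node[lab]
        except KeyError:
            raise TreeError(f"tip label {lab!r} not in tree") from None

    def tip_depths(self) -> np.ndarray:
        return self.depths[self.tip_ids]

    def is_ultrametric(self, rtol: float = ULTRAMETRIC_RTOL) -> bool:
        d = self.tip_depths()
        dmax = d.max()
        return dmax == 0 or (dmax - d.min()) <= rtol * dmax

    def is_ancestor(self, anc: int, node: int) -> bool:
        """True if ``anc`` is ``node`` or an ancestor of it (preorder ranges)."""
        return anc <= node < self.subtree_end[anc]

    # ------------------------------------------------------------------ queries
    def mrca(self, a: str, b: str) -> int:
        """Node id of the most recent common ancestor of two tips."""
        na, nb = self.node_of(a), self.node_of(b)
        u = na
        while not self.is_ancestor(u, nb):
            u = self.parent[u]
        return int(u)

    def path_length(self, a: str, b: str) -> float:
        """Patristic distance between two tips."""
        m = self.mrca(a, b)
        return float(
            self.depths[self.node_of(a)]
            + self.depths[self.node_of(b)]
            - 2.0 * self.depths[m]
        )

    # ------------------------------------------------------------------ vcv
    def _full_vcv(self) -> np.ndarray:
        if self._vcv_cache is None:
            k = self.n_tips
            C = np.zeros((k, k))
            for v in range(self.n_nodes):
                kids = self.children[v]
                if len(kids) < 2:
                    continue
                d = self.depths[v]
                ranges = [(self._tip_lo[c], self._tip_hi[c]) for c in kids]
                for i in range(len(ranges)):
                    a0, a1 = ranges[i]
                    for j in range(i + 1, len(ranges)):
                        b0, b1 = ranges[j]
                        C[a0:a1, b0:b1] = d
                        C[b0:b1, a0:a1] = d
            np.fill_diagonal(C, self.tip_depths())
            self._vcv_cache = C
        return self._vcv_cache

    def vcv(self, labels=None, lam: float | None = None) -> np.ndarray:
        """Phylogenetic variance-covariance matrix over ``labels``.

        ``C[i, j]`` is the root-to-MRCA depth of tips i and j; the diagonal
        holds root-to-tip depths. Restriction to a subset equals pruning then
        computing. With ``lam`` given, off-diagonals are scaled by lambda.
        """
        C = self._full_vcv()
        if labels is not None:
            idx = [self._tip_pos[self.node_of(l)] for l in labels]
            C = C[np.ix_(idx, idx)]
        C = C.copy()
        if lam is not None:
            C = apply_lambda(C, lam)
        return C

    # ------------------------------------------------------------------ transforms
    def rescale_lambda(self, lam: float) -> "Phylogeny":
        """Pagel's lambda branch-length transform of an ultrametric tree.

        Internal branches are multiplied by lambda; each pendant branch is
        stretched so the tip keeps its original depth. The covariance of the
        result equals ``apply_lambda`` on the original covariance. lambda = 1
        returns an identical tree; lambda = 0 a star phylogeny.
        """
        if not (0.0 <= lam <= 1.0):
            raise TreeError(f"lambda must be in [0, 1], got {lam}")
        if lam != 1.0 and not self.is_ultrametric():
            raise TreeError(
                "lambda branch rescaling requires an ultrametric tree "
                f"(tip depths vary by more than rtol={ULTRAMETRIC_RTOL})"
            )
        new = self.lengths * lam
        for i in self.tip_ids:
            if i == 0:
                continue
            new[i] = self.depths[i] - lam * self.depths[self.parent[i]]
        return Phylogeny(self.parent, new, self.labels)

    def prune(self, keep) -> "Phylogeny":
        """Restrict to the tips in ``keep``, collapsing degree-2 nodes.

        Collapsed chains sum their branch lengths; the root is always
        retained (so node depths, and hence the covariance submatrix, are
        preserved).
        """
        return self.prune_with_map(keep)[0]

    def prune_with_map(self, keep):
        """As :meth:`prune`, also returning ``old_id[new_node]``.

        A collapsed unary chain maps to its tipmost (most recent) retained
        node; the new root maps to the old root.
        """
        keep_nodes = {self.node_of(l) for l in keep}
        if not keep_nodes:
            raise TreeError("cannot prune to an empty tip set")
        count = np.zeros(self.n_nodes, dtype=np.intp)
        for i in self.tip_ids:
            if i in keep_nodes:
                count[i] = 1
        for i in range(self.n_nodes - 1, 0, -1):
            count[self.parent[i]] += count[i]

        parents: list[int] = [-1]
        lengths: list[float] = [0.0]
        labels: list[str | None] = [None]
        old_of: list[int] = [0]
        # stack entries: (old child node, new parent id, accumulated length)
        stack = []
        root_kids = [c for c in self.children[0] if count[c]]
        for c in reversed(root_kids):
            stack.append((c, 0, self.lengths[c]))
        while stack:
            old, newp, acc = stack.pop()
            kids = [c for c in self.children[old] if count[c]]
            if not kids:  # kept tip
                parents.append(newp)
                lengths.append(acc)
                labels.append(self.labels[old])
                old_of.append(old)
            elif len(kids) == 1:  # collapse degree-2 node
                stack.append((kids[0], newp, acc + self.lengths[kids[0]]))
            else:
                nid = len(parents)
                parents.append(newp)
                lengths.append(acc)
                labels.append(None)
                old_of.append(old)
                for c in reversed(kids):
                    stack.append((c, nid, self.lengths[c]))
        return Phylogeny(parents, lengths, labels), np.asarray(old_of, dtype=np.intp)

    # ------------------------------------------------------------------ I/O
    def to_newick(self) -> str:
        """Newick string with branch lengths (iterative; recursion-free)."""
        parts: dict[int, str] = {}
        for i in range(self.n_nodes - 1, -1, -1):
            if not self.children[i]:
                s = self.labels[i]
            else:
                s = "(" + ",".join(parts.pop(c) for c in self.children[i]) + ")"
            if i != 0:
                s += f":{self.lengths[i]:.10g}"
            parts[i] = s
        return parts[0] + ";"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return parse_newick(fh.read())

    def __repr__(self):  # pragma: no cover
        return f"<Phylogeny with {self.n_tips} tips, {self.n_nodes} nodes>"


def parse_newick(text: str) -> Phylogeny:
    """Parse a Newick string (branch lengths required on non-root nodes)."""
    import dendropy

    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from None

    parents: list[int] = []
    lengths: list[float] = []
    labels: list[str | None] = []
    ids: dict[int, int] = {}
    for nd in dtree.preorder_node_iter():
        nid = len(parents)
        ids[id(nd)] = nid
        if nd.parent_node is None:
            parents.append(-1)
            lengths.append(0.0)
        else:
            parents.append(ids[id(nd.parent_node)])
            if nd.edge.length is None:
                who = nd.taxon.label if nd.taxon else f"internal node {nid}"
                raise NewickParseError(f"missing branch length above {who!r}")
            lengths.append(float(nd.edge.length))
        lab = None
        if nd.taxon is not None:
            lab = nd.taxon.label
        elif nd.label and nd.is_leaf():
            lab = nd.label
        labels.append(lab)
    return Phylogeny(parents, lengths, labels)


def write_newick(tree: Phylogeny, path=None) -> str:
    """Serialize to Newick; optionally write to ``path``. Returns the string."""
    s = tree.to_newick()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


def apply_lambda(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel's lambda transform of a phylogenetic covariance matrix.

    Off-diagonal entries are multiplied by ``lam``; the diagonal is kept.
    lambda = 1 is the identity; lambda = 0 yields a diagonal (star) matrix.
    """
    if not (0.0 <= lam <= 1.0):
        raise TreeError(f"lambda must be in [0, 1], got {lam}")
    C = np.asarray(C, dtype=float)
    out = C * lam
    np.fill_diagonal(out, np.diagonal(C))
    return out
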