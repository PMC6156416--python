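import numpy as np
import pytest

import phylopred as pp


@pytest.fixture(scope="session")
def three_tip():
    """((A:1,B:1):1,C:2); — MRCA(A,B) at depth 1, all tips at depth 2."""
    return pp.parse_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture(scope="session")
def star_tree():
    return pp.parse_newick("(A:1,B:1,C:1):0;")


@pytest.fixture(scope="session")
def yule8():
    return pp.simulate_yule_tree(8, seed=801)


@pytest.fixture(scope="session")
def yule50():
    return pp.simulate_yule_tree(50, seed=501)


@pytest.fixture(scope="session")
def yule50_bm():
    """A lambda=1 Brownian trait on the 50-tip tree (sigma2=2)."""
    tree = pp.simulate_yule_tree(50, seed=501)
    table = pp.simulate_bm_traits(tree, lam=1.0, sigma2=2.0, seed=502)
    return tree, table.df["trait1"]


def brute_force_vcv(tree, labels):
    """Independent covariance oracle: per-pair root-to-MRCA path sums.

    Uses only mrca/path primitives plus explicit depth arithmetic, never
    the production vcv code path.
    """
    k = len(labels)
    C = np.zeros((k, k))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                node = tree.node_of(a)
                d = 0.0
                while node != 0:
                    d += tree.lengths[node]
                    node = tree.parent[node]
                C[i, i] = d
            else:
                m = tree.mrca(a, b)
                d = 0.0
                while m != 0:
                    d += tree.lengths[m]
                    m = tree.parent[m]
                C[i, j] = d
    return C
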