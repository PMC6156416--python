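"""Ancestral reconstruction and tip imputation."""

import numpy as np
import pandas as pd
import pytest

import phylopred as pp
from phylopred.errors import FitError


def brute_force_joint_gls(tree, tip_values):
    """Oracle: minimize sum (x_child - x_parent)^2 / length by least squares.

    Builds the weighted incidence system explicitly and solves with lstsq —
    structurally independent of the sparse-Laplacian production path.
    """
    n = tree.n_nodes
    tips = set(int(i) for i in tree.tip_ids)
    internal = [i for i in range(n) if i not in tips]
    col = {v: j for j, v in enumerate(internal)}
    rows, rhs = [], []
    for child in range(1, n):
        p = int(tree.parent[child])
        w = 1.0 / max(tree.lengths[child], 1e-12)
        row = np.zeros(len(internal))
        b = 0.0
        if child in tips:
            b -= np.sqrt(w) * tip_values[tree._tip_pos[child]]
        else:
            row[col[child]] += np.sqrt(w)
        row[col[p]] -= np.sqrt(w)
        rows.append(row)
        rhs.append(b)
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    out = np.zeros(n)
    for v, j in col.items():
        out[v] = sol[j]
    for i in tree.tip_ids:
        out[i] = tip_values[tree._tip_pos[int(i)]]
    return out


class TestReconstruction:
    def test_two_tip_inverse_length_weighting(self):
        t = pp.parse_newick("(A:1,B:3):0;")
        anc = pp.reconstruct_ancestral(np.array([0.0, 4.0]), t)
        # (0/1 + 4/3) / (1/1 + 1/3) = 1
        assert anc.states[0] == pytest.approx(1.0)

    def test_equal_branches_symmetry(self):
        t = pp.parse_newick("(A:2,B:2):0;")
        anc = pp.reconstruct_ancestral(np.array([0.0, 10.0]), t)
        assert anc.states[0] == pytest.approx(5.0)

    def test_matches_joint_gls_brute_force(self):
        tree = pp.simulate_yule_tree(6, seed=12)
        x = np.random.default_rng(13).normal(size=6)
        anc = pp.reconstruct_ancestral(x, tree)
        assert np.allclose(anc.states, brute_force_joint_gls(tree, x), atol=1e-8)

    def test_states_within_tip_range(self, yule50):
        x = np.random.default_rng(14).normal(size=50)
        anc = pp.reconstruct_ancestral(x, yule50)
        assert anc.states.min() >= x.min() - 1e-9
        assert anc.states.max() <= x.max() + 1e-9

    def test_requires_all_tips(self, yule8):
        with pytest.raises(FitError):
            pp.reconstruct_ancestral(np.r_[np.nan, np.ones(7)], yule8)


class TestPredictTip:
    def test_attachment_interpolates_on_pruned_branch(self):
        tree = pp.parse_newick("(((A:1,B:1):1,U:2):1,C:3):0;")
        vals = pd.Series({"A": 1.0, "B": 3.0, "C": 10.0})
        imp = pp.PhylogeneticImputer(tree=tree, lam=1.0).fit(vals)
        pred = imp.predict(["U"])
        # U's parent (depth 1) falls halfway along the pruned-tree branch
        # from the root (depth 0) to mrca(A,B) (depth 2): by hand, the
        # joint-GLS states are m = 30/11 and r = 62/11, midpoint 46/11
        pruned = tree.prune(["A", "B", "C"])
        anc = pp.reconstruct_ancestral(vals, pruned)
        assert anc.states[pruned.mrca("A", "B")] == pytest.approx(30 / 11)
        assert pred["predicted"].iloc[0] == pytest.approx(46 / 11, abs=1e-10)
        # path time below the attachment point: tip depth 3 minus depth 1
        assert pred["t"].iloc[0] == pytest.approx(2.0)

    def test_sister_interval_arithmetic(self):
        # pendant length 4, sigma2 forced to 1 -> half-width 1.96*sqrt(4)=3.92
        tree = pp.parse_newick("((U:4,A:4):1,B:5):0;")
        imp = pp.PhylogeneticImputer(tree=tree, lam=1.0).fit(
            pd.Series({"A": 2.0, "B": 6.0}))
        imp.sigma2_ = 1.0
        p = imp._predict_one("U")
        assert p.t == pytest.approx(4.0)
        assert p.ci_high - p.predicted == pytest.approx(3.92)
        assert p.ci_low <= p.predicted <= p.ci_high

    def test_zero_length_attachment_recovers_sister(self):
        tree = pp.parse_newick("((U:0,A:0):2,B:2):0;")
        p = pp.predict_tip("U", tree, pd.Series({"A": 7.5, "B": 1.0}), lam=1.0)
        assert p.predicted == pytest.approx(7.5)
        assert p.t == 0.0
        assert p.ci_low == p.ci_high == pytest.approx(7.5)

    def test_matches_gaussian_conditioning_oracle(self):
        """Masked tips equal brute-force conditional BM expectations (lam=1)."""
        tree = pp.simulate_yule_tree(12, seed=3)
        vals = pp.simulate_bm_traits(tree, lam=1.0, sigma2=1.5, seed=4).df["trait1"]
        masked = [tree.tip_labels[i] for i in (2, 5, 9)]
        measured = [t for t in tree.tip_labels if t not in masked]
        imp = pp.PhylogeneticImputer(tree=tree, lam=1.0).fit(vals.loc[measured])
        got = imp.predict(masked)["predicted"].to_numpy()

        C = tree.vcv(measured + masked)
        k = len(measured)
        Cinv = np.linalg.inv(C[:k, :k])
        xm = vals.loc[measured].to_numpy()
        one = np.ones(k)
        mu = (one @ Cinv @ xm) / (one @ Cinv @ one)
        cond = mu + C[k:, :k] @ Cinv @ (xm - mu)
        assert np.allclose(got, cond, atol=1e-8)

    def test_star_limit_predicts_phylogenetic_mean(self, yule50):
        vals = pp.simulate_bm_traits(yule50, lam=1.0, seed=21).df["trait1"]
        measured = yule50.tip_labels[:40]
        imp = pp.PhylogeneticImputer(tree=yule50, lam=0.0).fit(vals.loc[measured])
        preds = imp.predict()
        assert np.allclose(preds["predicted"], imp.mu_, atol=1e-9)
        depths = [yule50.depths[yule50.node_of(s)] for s in preds.index]
        assert np.allclose(preds["var"], np.asarray(depths) * imp.sigma2_, atol=1e-9)

    def test_equidistant_sisters_get_identical_predictions(self):
        tree = pp.parse_newick("(((U1:1,U2:1):1,A:2):1,(B:1.5,C:1.5):1.5):0;")
        vals = pd.Series({"A": 4.0, "B": 0.0, "C": 2.0})
        imp = pp.PhylogeneticImputer(tree=tree, lam=1.0).fit(vals)
        out = imp.predict(["U1", "U2"])
        assert out["predicted"].iloc[0] == pytest.approx(out["predicted"].iloc[1])
        assert out["ci_low"].iloc[0] == pytest.approx(out["ci_low"].iloc[1])

    def test_interval_monotone_in_t_and_sigma2(self):
        tree = pp.parse_newick("(((A:1,B:1):1,U:2):1,(C:2,V:2):1):0;")
        vals = pd.Series({"A": 1.0, "B": 2.0, "C": 5.0})
        imp = pp.PhylogeneticImputer(tree=tree, lam=1.0).fit(vals)
        out = imp.predict(["U", "V"]).sort_values("t")
        widths = (out["ci_high"] - out["ci_low"]).to_numpy()
        assert widths[0] <= widths[1] + 1e-12
        hw = widths[1]
        imp.sigma2_ *= 4.0
        out2 = imp.predict(["U", "V"]).sort_values("t")
        assert (out2["ci_high"] - out2["ci_low"]).to_numpy()[1] == pytest.approx(2 * hw)

    def test_measured_species_rejected(self, yule8):
        vals = pp.simulate_bm_traits(yule8, seed=1).df["trait1"]
        imp = pp.PhylogeneticImputer(tree=yule8).fit(vals)
        with pytest.raises(FitError, match="measured"):
            imp._predict_one(yule8.tip_labels[0])


class TestPredictAll:
    def test_counts(self, yule50):
        vals = pp.simulate_bm_traits(yule50, measured_fraction=0.7, seed=30).df["trait1"]
        preds = pp.predict_all(yule50, vals, None)
        assert len(preds) == 50 - vals.notna().sum()
        assert set(preds.index) | set(vals.dropna().index) == set(yule50.tip_labels)

    def test_all_measured_gives_empty(self, yule8):
        vals = pp.simulate_bm_traits(yule8, seed=31).df["trait1"]
        assert len(pp.predict_all(yule8, vals, None)) == 0


class TestRanking:
    def test_hand_ranked_toy(self):
        measured = pd.Series({"s1": 10.0, "s2": 1.0, "s3": 8.0})
        predicted = pd.Series({"s4": 9.0, "s5": 2.0, "s6": 0.5, "s3": 100.0})
        fam = {"s1": "F1", "s2": "F1", "s3": "F2", "s4": "F2", "s5": "F3", "s6": "F3"}
        out = pp.rank_nutrient_rich(measured, predicted, k=3, family_map=fam)
        # measured value of s3 (8.0) overrides its prediction; top-3 = s1, s4, s3
        assert out.loc["F2", "n_rich"] == 2
        assert out.loc["F1", "n_rich"] == 1
        assert out.loc["F3", "n_rich"] == 0
        assert out.loc["F1", "n_measured"] == 2
        assert int(out["n_total"].sum()) == 6

    def test_k_extremes(self):
        measured = pd.Series({"a": 3.0, "b": 2.0})
        predicted = pd.Series({"c": 1.0})
        fam = {"a": "X", "b": "Y", "c": "Y"}
        top1 = pp.rank_nutrient_rich(measured, predicted, 1, fam)
        assert top1.loc["X", "n_rich"] == 1 and top1["n_rich"].sum() == 1
        full = pp.rank_nutrient_rich(measured, predicted, 3, fam)
        assert (full["n_rich"] == full["n_total"]).all()
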