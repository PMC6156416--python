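"""PGLS regression: GLS algebra, OLS limit, inference, BLUP prediction."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import phylopred as pp
from phylopred.errors import FitError
from phylopred.pgls import gls_estimate


@pytest.fixture(scope="module")
def pgls_data(yule50):
    table = pp.simulate_pgls_data(yule50, betas=[2.0, 1.5, -0.7], lam=0.6,
                                  sigma2=1.0, seed=77)
    return yule50, table.df


class TestGlsAlgebra:
    def test_identity_covariance_equals_ols(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([np.ones(20), rng.normal(size=(20, 2))])
        y = rng.normal(size=20)
        est = gls_estimate(X, y, np.eye(20))
        ols = sm.OLS(y, X).fit()
        assert np.allclose(est["beta"], ols.params, atol=1e-12)
        assert np.allclose(est["se"], ols.bse, atol=1e-12)

    def test_intercept_only_is_gls_mean(self, yule8):
        rng = np.random.default_rng(2)
        y = rng.normal(size=8)
        C = yule8.vcv()
        est = gls_estimate(np.ones((8, 1)), y, C)
        Ci = np.linalg.inv(C)
        one = np.ones(8)
        assert est["beta"][0] == pytest.approx((one @ Ci @ y) / (one @ Ci @ one))

    def test_matches_explicit_normal_equations(self):
        """6-species, 2-predictor brute-force oracle with explicit inverses."""
        tree = pp.simulate_yule_tree(6, seed=66)
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(6), rng.normal(size=(6, 2))])
        y = rng.normal(size=6)
        C = pp.apply_lambda(tree.vcv(), 0.7)
        Vi = np.linalg.inv(C)
        beta_ref = np.linalg.inv(X.T @ Vi @ X) @ X.T @ Vi @ y
        est = gls_estimate(X, y, C)
        assert np.allclose(est["beta"], beta_ref, atol=1e-10)
        r = y - X @ beta_ref
        s2 = r @ Vi @ r / (6 - 3)
        assert np.allclose(est["se"], np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ Vi @ X))))

    def test_rank_deficiency_error(self, yule8):
        X = np.column_stack([np.ones(8), np.arange(8.0), 2 * np.arange(8.0)])
        with pytest.raises(FitError, match="rank"):
            gls_estimate(X, np.zeros(8), yule8.vcv())


class TestPglsEstimator:
    def test_lambda_zero_equals_ols_exactly(self, pgls_data):
        tree, df = pgls_data
        m = pp.PGLS(tree=tree, lam=0.0).fit(df[["pred1", "pred2"]],
                                            df["outcome"].to_numpy())
        X = sm.add_constant(df[["pred1", "pred2"]].to_numpy())
        ols = sm.OLS(df["outcome"].to_numpy(), X).fit()
        assert np.allclose(m.coef_, ols.params, atol=1e-10)
        assert np.allclose(m.se_, ols.bse, atol=1e-10)

    def test_ml_lambda_beats_boundaries(self, pgls_data):
        tree, df = pgls_data
        X, y = df[["pred1", "pred2"]], df["outcome"].to_numpy()
        m = pp.PGLS(tree=tree).fit(X, y)
        l0 = pp.PGLS(tree=tree, lam=0.0).fit(X, y).loglik_
        l1 = pp.PGLS(tree=tree, lam=1.0).fit(X, y).loglik_
        assert m.loglik_ >= max(l0, l1) - 1e-9
        assert 0.0 <= m.lambda_ <= 1.0

    def test_species_order_invariance(self, pgls_data):
        tree, df = pgls_data
        m1 = pp.PGLS(tree=tree).fit(df[["pred1", "pred2"]], df["outcome"].to_numpy())
        perm = df.sample(frac=1.0, random_state=0)
        m2 = pp.PGLS(tree=tree).fit(perm[["pred1", "pred2"]], perm["outcome"].to_numpy())
        assert np.allclose(m1.coef_, m2.coef_, atol=1e-8)
        assert m1.lambda_ == pytest.approx(m2.lambda_, abs=1e-6)
        assert m1.loglik_ == pytest.approx(m2.loglik_, abs=1e-8)

    def test_residual_orthogonality(self, pgls_data):
        tree, df = pgls_data
        m = pp.PGLS(tree=tree).fit(df[["pred1", "pred2"]], df["outcome"].to_numpy())
        Vi = np.linalg.inv(m._V)
        resid = m._y - m._X @ m.coef_
        assert np.allclose(m._X.T @ Vi @ resid, 0.0, atol=1e-8)

    def test_no_predictors_matches_signal_fit(self, yule50_bm):
        tree, values = yule50_bm
        sf = pp.fit_signal(values, tree)
        m = pp.PGLS(tree=tree).fit(np.empty((len(values), 0)), values.to_numpy(),
                                   species=list(values.index))
        assert m.coef_[0] == pytest.approx(sf.root_state, abs=1e-5)
        assert m.lambda_ == pytest.approx(sf.lambda_hat, abs=1e-4)

    def test_fit_pgls_from_table(self, yule50):
        table = pp.simulate_pgls_data(yule50, betas=[1.0, 0.5], lam=0.5, seed=8)
        fit = pp.fit_pgls(table, yule50, "outcome", ["pred1"])
        assert fit.n == 50
        assert len(fit.beta) == 2
        assert 0.0 <= fit.model_p <= 1.0


class TestPrediction:
    def test_zero_phylogenetic_covariance_reduces_to_regression(self):
        # species N diverges at the root: v0 = 0 against the training set
        tree = pp.parse_newick("(N:2,((A:1,B:1):0.5,C:1.5):0.5):0;")
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"x": rng.normal(size=3)}, index=["A", "B", "C"])
        y = 1.0 + 2.0 * df["x"].to_numpy() + rng.normal(size=3) * 0.1
        m = pp.PGLS(tree=tree, lam=1.0).fit(df, y, species=["A", "B", "C"])
        x0 = 0.37
        pred = m.predict(np.array([[x0]]), species=["N"], full_tree=tree)
        assert pred[0] == pytest.approx(m.coef_[0] + m.coef_[1] * x0, abs=1e-10)

    def test_lambda_zero_variance_is_ols_leverage_form(self, pgls_data):
        tree, df = pgls_data
        train = df.iloc[1:]
        m = pp.PGLS(tree=tree, lam=0.0).fit(train[["pred1", "pred2"]],
                                            train["outcome"].to_numpy(),
                                            species=list(train.index))
        x0 = train[["pred1", "pred2"]].mean().to_numpy()
        out = m.predict(x0[None, :], species=[df.index[0]], interval=True,
                        full_tree=tree)
        Xo = sm.add_constant(train[["pred1", "pred2"]].to_numpy())
        ols = sm.OLS(train["outcome"].to_numpy(), Xo).fit()
        x0full = np.r_[1.0, x0]
        var_ref = ols.mse_resid * (1.0 + x0full @ np.linalg.inv(Xo.T @ Xo) @ x0full)
        assert out["var"].iloc[0] == pytest.approx(var_ref, rel=1e-8)
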