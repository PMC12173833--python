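import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import dendropy

from tedyn.io_formats import PhyloTree
from tedyn.pgls import (
    aicc_from_loglik,
    ancestral_states,
    compare_models,
    fit_pgls,
)
from tedyn.synthetic_data import (
    TraitSimSpec,
    read_tree_from_string,
    simulate_bm_trait,
    simulate_tree,
)


def _star_tree(n=6):
    nwk = "(" + ",".join(f"s{i}:1" for i in range(n)) + ");"
    t = dendropy.Tree.get(data=nwk, schema="newick", suppress_internal_node_taxa=True)
    return PhyloTree(t)


def _ols(y, X):
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    return beta


@pytest.fixture(scope="module")
def eight_tip():
    return simulate_tree(8, seed=21)


@pytest.fixture(scope="module")
def regression_data(eight_tip):
    rng = np.random.default_rng(1)
    labels = eight_tip.tip_labels
    x = pd.Series(rng.normal(size=8), index=labels, name="x")
    y = 2.0 + 1.5 * x + simulate_bm_trait(eight_tip, TraitSimSpec(), seed=2).iloc[0]
    y.name = "y"
    return y, x.to_frame()


class TestFit:
    def test_lambda_zero_equals_ols(self, eight_tip, regression_data):
        y, X = regression_data
        fit = fit_pgls(eight_tip, y, X, lambda_mode=0.0)
        beta = _ols(y.reindex(eight_tip.tip_labels).to_numpy(),
                    X.reindex(eight_tip.tip_labels).to_numpy())
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_star_tree_any_lambda_equals_ols(self, regression_data):
        star = _star_tree(8)
        y, X = regression_data
        y = pd.Series(y.to_numpy(), index=star.tip_labels, name="y")
        X = pd.DataFrame({"x": X["x"].to_numpy()}, index=star.tip_labels)
        beta = _ols(y.to_numpy(), X.to_numpy())
        for lam in (0.0, 0.5, 1.0):
            fit = fit_pgls(star, y, X, lambda_mode=lam)
            np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_lambda_one_matches_dense_gls_oracle(self, eight_tip, regression_data):
        y, X = regression_data
        fit = fit_pgls(eight_tip, y, X, lambda_mode=1.0)
        labels = eight_tip.tip_labels
        C = eight_tip.cov_matrix(labels)
        Xd = np.column_stack([np.ones(8), X.reindex(labels).to_numpy().ravel()])
        yv = y.reindex(labels).to_numpy()
        Ci = np.linalg.inv(C)
        beta = np.linalg.inv(Xd.T @ Ci @ Xd) @ Xd.T @ Ci @ yv
        np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)

    def test_ml_profile_beats_lambda_grid(self, eight_tip, regression_data):
        y, X = regression_data
        fit = fit_pgls(eight_tip, y, X, lambda_mode="ML")
        for lam in (0.0, 0.25, 0.5, 0.75, 1.0):
            fixed = fit_pgls(eight_tip, y, X, lambda_mode=lam)
            assert fit.loglik >= fixed.loglik - 1e-6

    def test_rank_deficiency_names_column(self, eight_tip, regression_data):
        y, X = regression_data
        X2 = X.assign(x_copy=X["x"])
        with pytest.raises(ValueError, match="aliased"):
            fit_pgls(eight_tip, y, X2, lambda_mode=1.0)

    def test_tip_mismatch_rejected(self, eight_tip, regression_data):
        y, X = regression_data
        with pytest.raises(ValueError, match="tip set"):
            fit_pgls(eight_tip, y.iloc[:-1], X, lambda_mode=1.0)

    def test_categorical_dummy_coding_reference_level(self, eight_tip):
        labels = eight_tip.tip_labels
        site = pd.Series(
            pd.Categorical(
                ["inside"] * 4 + ["outside"] * 4, categories=["inside", "outside"]
            ),
            index=labels, name="site",
        )
        y = pd.Series(
            [1.0, 1.2, 0.8, 1.1, 5.0, 5.2, 4.9, 5.1], index=labels, name="y"
        )
        fit = fit_pgls(eight_tip, y, site.to_frame(), lambda_mode=0.0)
        assert "site[outside]" in fit.params.index
        assert fit.params["site[outside]"] == pytest.approx(
            y.iloc[4:].mean() - y.iloc[:4].mean(), abs=1e-8
        )


class TestAicc:
    def test_arithmetic_spot_check(self):
        assert aicc_from_loglik(-40.0, 3, 11) == pytest.approx(89.4286, abs=1e-4)

    def test_undefined_for_saturated_model(self):
        with pytest.raises(ValueError):
            aicc_from_loglik(-1.0, 10, 11)

    def test_identical_fits_have_zero_delta(self, eight_tip, regression_data):
        y, X = regression_data
        f1 = fit_pgls(eight_tip, y, X, lambda_mode=1.0)
        f2 = fit_pgls(eight_tip, y, X, lambda_mode=1.0)
        table = compare_models([f1, f2])
        assert (table["delta_aicc"] == 0).all()

    def test_mismatched_tipsets_rejected(self, eight_tip, regression_data):
        y, X = regression_data
        other = simulate_tree(8, seed=99)
        y2 = pd.Series(y.to_numpy(), index=other.tip_labels, name="y")
        X2 = pd.DataFrame({"x": X["x"].to_numpy()}, index=other.tip_labels)
        f1 = fit_pgls(eight_tip, y, X, lambda_mode=1.0)
        f2 = fit_pgls(other, y2, X2, lambda_mode=1.0)
        with pytest.raises(ValueError):
            compare_models([f1, f2])

    def test_true_model_selected_most_of_the_time(self):
        tree = simulate_tree(11, seed=13)
        labels = tree.tip_labels
        rng = np.random.default_rng(8)
        wins = 0
        n_rep = 60
        for rep in range(n_rep):
            x1 = pd.Series(rng.normal(size=11), index=labels, name="x1")
            x2 = pd.Series(
                pd.Categorical(rng.permutation(["inside"] * 6 + ["outside"] * 5),
                               categories=["inside", "outside"]),
                index=labels, name="x2",
            )
            noise = simulate_bm_trait(
                tree, TraitSimSpec(sigma2=0.25), seed=int(rng.integers(2**31))
            ).iloc[0]
            y = 1.0 + 3.0 * x1 + 4.0 * (x2 == "outside") + noise
            y.name = "y"
            fits = [
                fit_pgls(tree, y, pd.DataFrame({"x1": x1}), "ML"),
                fit_pgls(tree, y, pd.DataFrame({"x2": x2}), "ML"),
                fit_pgls(tree, y, pd.DataFrame({"x1": x1, "x2": x2}), "ML"),
            ]
            best = compare_models(fits)["model"].iloc[0]
            wins += "x1" in best and "x2" in best
        assert wins / n_rep >= 0.9


class TestAncestralStates:
    def test_constant_tips_reconstruct_constant(self, balanced16):
        y = pd.Series(3.25, index=balanced16.tip_labels)
        rec = ancestral_states(balanced16, y)
        np.testing.assert_allclose(rec["estimate"], 3.25, atol=1e-10)

    def test_two_tip_symmetric_root_is_mean(self):
        tree = read_tree_from_string("(a:1,b:1);")
        rec = ancestral_states(tree, pd.Series({"a": 2.0, "b": 6.0}))
        assert rec["estimate"].iloc[0] == pytest.approx(4.0, abs=1e-10)

    def test_root_equals_phylogenetic_mean(self, yule11):
        y = simulate_bm_trait(yule11, TraitSimSpec(), seed=6).iloc[0]
        rec = ancestral_states(yule11, y)
        C = yule11.cov_matrix(yule11.tip_labels)
        Ci = np.linalg.inv(C)
        ones = np.ones(11)
        mu = (ones @ Ci @ y.reindex(yule11.tip_labels).to_numpy()) / (ones @ Ci @ ones)
        assert rec["estimate"].iloc[0] == pytest.approx(mu, abs=1e-8)

    def test_matches_squared_change_parsimony_oracle(self):
        tree = simulate_tree(6, seed=17)
        y = simulate_bm_trait(tree, TraitSimSpec(), seed=3).iloc[0]
        rec = ancestral_states(tree, y)
        # oracle: numerically minimize sum (delta x)^2 / branch length
        dt = tree.dendropy_tree
        internals = [n for n in dt.preorder_internal_node_iter()]
        idx = {n.label: i for i, n in enumerate(internals)}
        tipv = dict(y)

        def objective(x):
            total = 0.0
            for node in dt.preorder_node_iter():
                if node.parent_node is None:
                    continue
                pv = x[idx[node.parent_node.label]]
                cv = (
                    tipv[node.taxon.label]
                    if node.is_leaf()
                    else x[idx[node.label]]
                )
                total += (cv - pv) ** 2 / node.edge.length
            return total

        x0 = np.full(len(internals), y.mean())
        sol = optimize.minimize(objective, x0, method="BFGS", tol=1e-12)
        oracle = pd.Series(sol.x, index=[n.label for n in internals])
        np.testing.assert_allclose(
            rec["estimate"].to_numpy(), oracle.reindex(rec.index).to_numpy(),
            atol=1e-5,
        )

    def test_variances_positive_away_from_tips(self, yule11):
        y = simulate_bm_trait(yule11, TraitSimSpec(), seed=8).iloc[0]
        rec = ancestral_states(yule11, y)
        assert (rec["variance"] >= 0).all()
        assert rec["variance"].iloc[0] > 0
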