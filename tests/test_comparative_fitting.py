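"""Likelihoods, model fitting, signal estimation, ancestral states, simulation."""

import math

import numpy as np
import pandas as pd
import pytest

import waxphylo as wp
from waxphylo.comparative import single_regime_painting

from conftest import dense_mvn_loglik, random_tree, shared_path_vcv


def trait(tree: wp.Phylogeny, values) -> pd.Series:
    return pd.Series(np.asarray(values, dtype=float), index=tree.tip_labels)


class TestBmLikelihood:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_mvn(self, seed):
        rng = np.random.default_rng(seed)
        t = random_tree(rng, int(rng.integers(4, 9)))
        x = trait(t, rng.normal(size=t.n_tips))
        s2, z0 = float(rng.uniform(0.5, 2.0)), float(rng.normal())
        dense = dense_mvn_loglik(x.to_numpy(), np.full(t.n_tips, z0),
                                 s2 * shared_path_vcv(t))
        assert wp.bm_loglik(t, x, s2, z0) == pytest.approx(dense, abs=1e-8)

    def test_two_tip_closed_form_fit(self):
        """Independent unit branches, x = (0, 2): z0 = 1, sigma2 = 1,
        lnL = -(log(2 pi) + 1)."""
        t = wp.read_newick("(A:1,B:1);")
        fit = wp.fit_brownian(t, trait(t, [0.0, 2.0]))
        assert fit.z0 == pytest.approx(1.0)
        assert fit.sigma2 == pytest.approx(1.0)
        assert fit.lnl == pytest.approx(-(math.log(2 * math.pi) + 1), abs=1e-12)
        assert fit.lnl == pytest.approx(-2.8379, abs=1e-4)

    def test_constant_traits_flagged_degenerate(self):
        t = wp.simulate_tree(6, seed=0)
        fit = wp.fit_brownian(t, trait(t, np.full(6, 3.0)))
        assert "degenerate_zero_variance" in fit.flags
        assert fit.sigma2 == 0.0

    def test_fit_maximizes_likelihood(self):
        t = wp.simulate_tree(30, seed=1)
        x = wp.simulate_bm(t, sigma2=2.0, z0=1.0, seed=5)
        fit = wp.fit_brownian(t, x)
        for ds2, dz0 in [(1.05, 1.0), (0.95, 1.0), (1.0, 1.02), (1.0, 0.98)]:
            assert wp.bm_loglik(t, x, fit.sigma2 * ds2, fit.z0 * dz0) <= fit.lnl + 1e-9


class TestPagelsLambda:
    def test_bm_traits_high_lambda(self):
        t = wp.simulate_tree(100, seed=10)
        x = wp.simulate_bm(t, sigma2=1.0, z0=0.0, seed=11)
        res = wp.fit_lambda(t, x, n_randomizations=0)
        assert res.lambda_hat > 0.85
        assert res.lnl_lambda >= res.lnl_zero

    def test_shuffled_traits_low_lambda(self):
        t = wp.simulate_tree(100, seed=10)
        rng = np.random.default_rng(12)
        lams = []
        for _ in range(5):
            x = trait(t, rng.permutation(
                wp.simulate_bm(t, 1.0, 0.0, seed=13).to_numpy()))
            lams.append(wp.fit_lambda(t, x, n_randomizations=0).lambda_hat)
        assert np.median(lams) < 0.2

    def test_permutation_p_floor(self):
        """Strong signal: no permutation beats the observed improvement,
        so p hits its floor 1 / (B + 1)."""
        t = wp.simulate_tree(50, seed=20)
        x = wp.simulate_bm(t, sigma2=1.0, z0=0.0, seed=21)
        res = wp.fit_lambda(t, x, n_randomizations=25, seed=22)
        assert res.p_value == pytest.approx(1 / 26)

    def test_too_few_tips_errors(self, three_tip_tree):
        with pytest.raises(ValueError):
            wp.fit_lambda(three_tip_tree, trait(three_tip_tree, [0, 1, 2]))


class TestOuLikelihoodAndFit:
    @pytest.mark.parametrize("seed", range(5))
    def test_ou_loglik_matches_dense_mvn(self, seed):
        rng = np.random.default_rng(200 + seed)
        t = random_tree(rng, int(rng.integers(4, 9)))
        painting = wp.paint_regimes(t, [(1, t.tip_labels[:2])])
        alpha = float(rng.uniform(0.3, 3.0))
        s2 = float(rng.uniform(0.5, 2.0))
        theta = rng.normal(size=2) * 3
        z0 = float(rng.normal())
        x = trait(t, rng.normal(size=t.n_tips))
        W = wp.ou_expectation_weights(t, painting, alpha)
        mean = W[:, 0] * z0 + W[:, 1:] @ theta
        V = wp.ou_covariance(t, alpha, s2)
        dense = dense_mvn_loglik(x.to_numpy(), mean, V)
        assert wp.ou_loglik(t, x, painting, alpha, s2, theta, z0) == \
            pytest.approx(dense, abs=1e-8)

    def test_bm_limit_of_ou(self):
        t = wp.simulate_tree(20, seed=30)
        x = wp.simulate_bm(t, 1.5, 0.5, seed=31)
        bm = wp.fit_brownian(t, x)
        lnl_ou = wp.ou_loglik(t, x, single_regime_painting(t), 1e-8,
                              bm.sigma2, np.array([bm.z0]), bm.z0)
        assert abs(lnl_ou - bm.lnl) < 1e-3

    def test_single_optimum_recovery(self):
        t = wp.simulate_tree(200, seed=40)
        painting = single_regime_painting(t)
        x = wp.simulate_ou(t, painting, alpha=2.0, sigma2=1.0,
                           theta=np.array([5.0]), z0=5.0, seed=41)
        fit = wp.fit_ou(t, x, painting)
        assert 4.5 <= fit.theta[0] <= 5.5
        assert 1.0 <= fit.alpha <= 4.0

    @staticmethod
    def _midsize_clade_tips(t: wp.Phylogeny) -> list[str]:
        for v in range(1, t.n_nodes):
            tips = [u for u in t.subtree_nodes(v) if not t.children[u]]
            if 8 <= len(tips) <= t.n_tips // 2:
                return [t.labels[u] for u in tips]
        raise AssertionError("no mid-size clade on this tree")

    def test_profile_fit_beats_nearby_parameters(self):
        t = wp.simulate_tree(40, seed=42)
        painting = wp.paint_regimes(t, [(1, self._midsize_clade_tips(t))])
        x = wp.simulate_ou(t, painting, 1.5, 1.0, np.array([0.0, 4.0]),
                           z0=0.0, seed=43)
        fit = wp.fit_ou(t, x, painting)
        base = wp.ou_loglik(t, x, painting, fit.alpha, fit.sigma2,
                            fit.theta, fit.z0)
        assert base == pytest.approx(fit.lnl, abs=1e-8)
        for fac in (0.9, 1.1):
            assert wp.ou_loglik(t, x, painting, fit.alpha * fac, fit.sigma2,
                                fit.theta, fit.z0) <= fit.lnl + 1e-9

    def test_parameter_counts_follow_ouch_convention(self, default_dataset):
        ds = default_dataset
        x = ds.latent
        ou1 = wp.fit_ou(ds.tree, x, single_regime_painting(ds.tree))
        ou3 = wp.fit_ou(ds.tree, x, ds.painting)
        est = wp.fit_ou(ds.tree, x, ds.painting, root_mode="estimated")
        assert (ou1.k, ou3.k, est.k) == (3, 5, 6)

    def test_unvisited_regime_errors(self):
        t = wp.simulate_tree(8, seed=44)
        lone = t.tip_labels[0]
        painting = wp.paint_regimes(t, [(1, [lone])])
        x = wp.simulate_bm(t, 1.0, 0.0, seed=45).drop(lone)
        with pytest.raises(ValueError, match="non-identifiable"):
            wp.fit_ou(t, x, painting)


class TestAicc:
    def test_formula_value(self):
        assert wp.aicc(0.0, 1, 10) == pytest.approx(2.5)

    def test_large_n_limit_is_plain_aic(self):
        assert wp.aicc(-10.0, 3, 10**9) == pytest.approx(20 + 6, abs=1e-6)

    def test_small_n_errors(self):
        with pytest.raises(ValueError):
            wp.aicc(0.0, 3, 4)

    def test_compare_models_order_invariant(self, default_dataset):
        ds = default_dataset
        fits = [wp.fit_brownian(ds.tree, ds.latent),
                wp.fit_ou(ds.tree, ds.latent, ds.painting)]
        t1 = wp.compare_models(fits)
        t2 = wp.compare_models(fits[::-1])
        assert list(t1["model"]) == list(t2["model"])
        assert t1["delta_aicc"].iloc[0] == 0.0


class TestAncestralStates:
    def test_two_tip_symmetry(self):
        t = wp.read_newick("(A:1,B:1);")
        anc = wp.ancestral_states(t, trait(t, [0.0, 2.0]))
        root = anc[~anc["is_tip"]].iloc[0]
        assert root["value"] == pytest.approx(1.0)

    def test_constant_traits(self):
        t = wp.simulate_tree(8, seed=50)
        anc = wp.ancestral_states(t, trait(t, np.full(8, 2.5)))
        assert np.allclose(anc["value"], 2.5)

    def test_matches_joint_gls_oracle(self):
        """Conditioning the joint tip/ancestor MVN built from first
        principles reproduces the reconstruction."""
        rng = np.random.default_rng(51)
        t = random_tree(rng, 5)
        x = trait(t, rng.normal(size=5))
        fit = wp.fit_brownian(t, x)
        M = np.zeros((t.n_nodes, t.n_nodes))
        paths = {}
        for v in range(t.n_nodes):
            p, u = [], v
            while u != 0:
                p.append(u)
                u = t.parent[u]
            paths[v] = set(p)
        for a in range(t.n_nodes):
            for b in range(t.n_nodes):
                M[a, b] = sum(t.blen[v] for v in paths[a] & paths[b])
        tips = list(t.tips)
        obs = [tips.index(v) for v in t.tips]
        Ct = M[np.ix_(t.tips, t.tips)]
        anc = wp.ancestral_states(t, x)
        internal = anc[~anc["is_tip"]]
        for _, row in internal.iterrows():
            v = int(row["node"])
            s = M[v, t.tips]
            expected = fit.z0 + s @ np.linalg.solve(Ct, x.to_numpy() - fit.z0)
            assert row["value"] == pytest.approx(expected, abs=1e-8)

    def test_annotated_newick_contains_values(self):
        t = wp.read_newick("(A:1,B:1);")
        anc = wp.ancestral_states(t, trait(t, [0.0, 2.0]))
        text = wp.comparative.annotated_newick(t, anc)
        assert "[&value=" in text


class TestSimulation:
    def test_zero_variance_bm_is_constant(self):
        t = wp.simulate_tree(5, seed=60)
        x = wp.simulate_bm(t, sigma2=0.0, z0=1.5, seed=61)
        assert np.allclose(x, 1.5)

    def test_zero_variance_ou_follows_mean_path(self):
        t = wp.read_newick("(A:2,B:2);")
        p = single_regime_painting(t)
        x = wp.simulate_ou(t, p, alpha=1.0, sigma2=0.0,
                           theta=np.array([4.0]), z0=0.0, seed=62)
        expected = 4.0 * (1 - math.exp(-2.0))
        assert np.allclose(x, expected)

    def test_ou_stationary_moments(self):
        """Many replicate tips on long independent branches approach the
        stationary distribution N(theta, sigma2 / (2 alpha))."""
        n = 8000
        parent = np.concatenate([[-1], np.zeros(n, dtype=int)])
        blen = np.concatenate([[0.0], np.full(n, 10.0)])
        labels = {i: f"t{i}" for i in range(1, n + 1)}
        t = wp.Phylogeny(parent, blen, labels)
        p = single_regime_painting(t)
        x = wp.simulate_ou(t, p, alpha=1.0, sigma2=2.0,
                           theta=np.array([3.0]), z0=0.0, seed=63)
        assert x.mean() == pytest.approx(3.0, abs=0.05)
        assert x.var() == pytest.approx(1.0, rel=0.05)

    def test_bm_empirical_covariance(self, three_tip_tree):
        reps = np.array([
            wp.simulate_bm(three_tip_tree, 1.0, 0.0, seed=1000 + i).to_numpy()
            for i in range(8000)
        ])
        emp = np.cov(reps, rowvar=False)
        C = wp.vcv_matrix(three_tip_tree)
        assert np.allclose(emp, C, atol=0.05 * C.max() + 0.02)

    def test_seed_determinism(self):
        t = wp.simulate_tree(10, seed=70)
        a = wp.simulate_bm(t, 1.0, 0.0, seed=71)
        b = wp.simulate_bm(t, 1.0, 0.0, seed=71)
        pd.testing.assert_series_equal(a, b)
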