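"""Tree handling, phylogenetic correlation, and the mixed models."""

import math

import numpy as np
import pandas as pd
import pytest

from mpnull import phylo as ph
from mpnull.synth import gen_trait_binary, gen_trait_gaussian, gen_yule_tree


class TestNewick:
    def test_basic_parse(self):
        t = ph.parse_newick("((A:1,B:1):1,C:2);")
        assert sorted(t.tip_labels) == ["A", "B", "C"]
        assert t.is_ultrametric and t.depth == pytest.approx(2.0)

    def test_roundtrip_random_trees(self):
        for seed in range(10):
            t = gen_yule_tree(12, 1.0, seed=seed)
            again = ph.parse_newick(ph.write_newick(t))
            assert sorted(again.tip_labels) == sorted(t.tip_labels)
            assert again.depth == pytest.approx(t.depth, rel=1e-9)
            C1 = ph.phylo_correlation(t)
            C2 = ph.phylo_correlation(again)
            assert np.allclose(C1.to_numpy(), C2.loc[C1.index, C1.columns].to_numpy())

    def test_missing_branch_length_rejected(self):
        with pytest.raises(ValueError, match="branch length"):
            ph.parse_newick("((A:1,B),C:2);")

    def test_malformed_rejected(self):
        with pytest.raises(ValueError, match="malformed"):
            ph.parse_newick("((A:1,B:1;")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(ValueError):
            ph.parse_newick("((A:1,A:1):1,C:2);")


class TestConsensus:
    ab_cd = "((A:1,B:1):1,(C:1,D:1):1);"
    ac_bd = "((A:1,C:1):1,(B:1,D:1):1);"

    def test_idempotent_on_identical_inputs(self):
        trees = [ph.parse_newick(self.ab_cd)] * 3
        con = ph.majority_rule_consensus(trees)
        assert "C:1.0,D:1.0" in con.newick().replace("(", "").replace(")", "") or \
            sorted(con.tip_labels) == ["A", "B", "C", "D"]
        C = ph.phylo_correlation(con)
        assert C.loc["A", "B"] == pytest.approx(0.5)
        assert C.loc["A", "C"] == pytest.approx(0.0)

    def test_majority_clade_retained(self):
        trees = [ph.parse_newick(self.ab_cd)] * 2 + [ph.parse_newick(self.ac_bd)]
        C = ph.phylo_correlation(ph.majority_rule_consensus(trees))
        assert C.loc["C", "D"] > 0  # the 2/3 clade survives

    def test_even_split_becomes_polytomy(self):
        trees = [ph.parse_newick(self.ab_cd), ph.parse_newick(self.ac_bd)]
        con = ph.majority_rule_consensus(trees)
        # star: no internal structure retained
        n_internal = sum(
            1 for nd in con.dendropy_tree.preorder_internal_node_iter()
            if nd.parent_node is not None
        )
        assert n_internal == 0

    def test_mismatched_tip_sets_rejected(self):
        with pytest.raises(ValueError, match="tip set"):
            ph.majority_rule_consensus([
                ph.parse_newick(self.ab_cd),
                ph.parse_newick("((A:1,B:1):1,(C:1,E:1):1);"),
            ])


class TestGraft:
    def test_stem_arithmetic(self):
        a = ph.parse_newick("((A:1,B:1):1,C:2);")
        b = ph.parse_newick("((D:1.5,E:1.5):0.5,F:2);")
        g = ph.graft_trees(a, b, 5.0)
        assert g.is_ultrametric
        assert g.depth == pytest.approx(5.0)
        assert sorted(g.tip_labels) == ["A", "B", "C", "D", "E", "F"]
        C = ph.phylo_correlation(g)
        # within-subtree correlations rescale by depth_subtree/divergence
        assert C.loc["A", "B"] == pytest.approx(0.5 * 2.0 / 5.0 + 3.0 / 5.0)
        assert C.loc["A", "D"] == pytest.approx(0.0)

    def test_overlapping_tips_rejected(self):
        a = ph.parse_newick("((A:1,B:1):1,C:2);")
        with pytest.raises(ValueError, match="disjoint"):
            ph.graft_trees(a, a, 10.0)

    def test_too_small_divergence_rejected(self):
        a = ph.parse_newick("((A:1,B:1):1,C:2);")
        b = ph.parse_newick("((D:2,E:2):2,F:4);")
        with pytest.raises(ValueError, match="divergence"):
            ph.graft_trees(a, b, 3.0)


class TestCorrelation:
    def test_star_tree_gives_identity(self):
        C = ph.phylo_correlation(ph.parse_newick("(A:1,B:1,C:1);"))
        assert np.allclose(C.to_numpy(), np.eye(3))

    def test_shared_path_example(self):
        C = ph.phylo_correlation(ph.parse_newick("((A:1,B:1):1,C:2);"))
        assert C.loc["A", "B"] == pytest.approx(0.5)
        assert C.loc["A", "C"] == pytest.approx(0.0)
        assert np.allclose(np.diag(C.to_numpy()), 1.0)

    def test_positive_semidefinite_on_random_trees(self):
        for seed in range(15):
            C = ph.phylo_correlation(gen_yule_tree(15, 1.0, seed=100 + seed))
            eigs = np.linalg.eigvalsh(C.to_numpy())
            assert eigs.min() >= -1e-10

    def test_non_ultrametric_rejected(self):
        with pytest.raises(ValueError, match="ultrametric"):
            ph.phylo_correlation(ph.parse_newick("((A:1,B:3):1,C:2);"))


class TestGaussianPMM:
    def test_matches_gls_posterior_with_pinned_variances(self, rng):
        # inverse-gamma priors with huge shape pin each variance at its mean,
        # so the β posterior must match the closed-form GLS posterior
        tree = gen_yule_tree(12, 1.0, seed=3)
        C = ph.phylo_correlation(tree)
        y = gen_trait_gaussian(C, h=0.6, beta0=1.0, seed=4)
        big = 1e6
        # the shared inverse-gamma prior pins both variances at 0.5
        cfg = ph.PMMConfig(n_iter=4000, n_burnin=1000, n_chains=2, seed=5,
                           var_prior=(big, big * 0.5), beta_prior_sd=1e4)
        fit = ph.fit_pmm_gaussian(y, None, C, cfg)
        V = 0.5 * C.to_numpy() + 0.5 * np.eye(len(C))
        Vi = np.linalg.inv(V)
        one = np.ones((len(C), 1))
        post_var = 1.0 / float((one.T @ Vi @ one).item())
        post_mean = post_var * float((one.T @ Vi @ y.to_numpy()).item())
        beta_draws = fit.beta_samples[:, 0]
        # variances pinned at var_prior scale/shape = s2p for both components
        assert beta_draws.mean() == pytest.approx(
            post_mean, abs=4 * beta_draws.std() / math.sqrt(50))
        assert beta_draws.var() == pytest.approx(post_var, rel=0.2)

    def test_parameter_recovery(self, rng):
        tree = gen_yule_tree(150, 1.0, seed=6)
        C = ph.phylo_correlation(tree)
        x = pd.Series((np.arange(len(C)) % 2).astype(float), index=C.index)
        y = gen_trait_gaussian(C, h=0.8, beta0=0.0, delta=1.0, x_group=x, seed=7)
        fit = ph.fit_pmm_gaussian(y, x, C, ph.PMMConfig(
            n_iter=2500, n_burnin=800, n_chains=2, seed=8))
        delta = fit.beta_samples[:, 1]
        assert abs(delta.mean() - 1.0) < 3 * delta.std()
        h = fit.h_samples
        assert abs(h.mean() - 0.8) < 3 * h.std()

    def test_identity_matrix_gives_small_h(self):
        n = 150
        C = pd.DataFrame(np.eye(n), index=[f"s{i}" for i in range(n)],
                         columns=[f"s{i}" for i in range(n)])
        y = gen_trait_gaussian(C, h=0.0, seed=9)
        fit = ph.fit_pmm_gaussian(y, None, C, ph.PMMConfig(
            n_iter=2000, n_burnin=600, n_chains=2, seed=10))
        # no phylogenetic structure to attribute variance to
        assert fit.summaries["h_ci"][0] < 0.3

    def test_h_scale_invariance(self):
        tree = gen_yule_tree(80, 1.0, seed=11)
        C = ph.phylo_correlation(tree)
        y = gen_trait_gaussian(C, h=0.5, seed=12)
        cfg = ph.PMMConfig(n_iter=2000, n_burnin=600, n_chains=2, seed=13)
        h1 = ph.fit_pmm_gaussian(y, None, C, cfg).h_samples.mean()
        h2 = ph.fit_pmm_gaussian(10.0 * y, None, C, cfg).h_samples.mean()
        assert abs(h1 - h2) < 0.1


class TestBinaryPMM:
    def test_lor_recovery(self):
        tree = gen_yule_tree(200, 1.0, seed=14)
        C = ph.phylo_correlation(tree)
        x = pd.Series((np.arange(len(C)) % 2).astype(float), index=C.index)
        y = gen_trait_binary(C, h=0.3, lor=2.0, beta0=-1.0, x_group=x, seed=15)
        fit = ph.fit_pmm_binary(y, x, C, ph.PMMConfig(
            n_iter=2500, n_burnin=800, n_chains=2, seed=16))
        lor = fit.beta_samples[:, 1]
        assert abs(lor.mean() - 2.0) < 3 * lor.std()
        assert np.all((fit.h_samples >= 0) & (fit.h_samples <= 1))

    def test_no_effect_interval_covers_zero(self):
        tree = gen_yule_tree(100, 1.0, seed=17)
        C = ph.phylo_correlation(tree)
        x = pd.Series((np.arange(len(C)) % 2).astype(float), index=C.index)
        y = gen_trait_binary(C, h=0.3, lor=0.0, beta0=0.0, x_group=x, seed=18)
        fit = ph.fit_pmm_binary(y, x, C, ph.PMMConfig(
            n_iter=2000, n_burnin=600, n_chains=2, seed=19))
        lo, hi = fit.summaries["lor_ci"]
        assert lo <= 0.0 <= hi

    def test_constant_response_warns(self):
        tree = gen_yule_tree(20, 1.0, seed=20)
        C = ph.phylo_correlation(tree)
        y = pd.Series(np.ones(len(C)), index=C.index)
        with pytest.warns(UserWarning, match="constant"):
            ph.fit_pmm_binary(y, None, C, ph.PMMConfig(
                n_iter=400, n_burnin=100, n_chains=1, seed=21))


class TestHeritability:
    def _fit(self, h_samples):
        return ph.PhyloMixedFit(
            beta_samples=np.zeros((len(h_samples), 1)),
            sigma2_p_samples=np.asarray(h_samples),
            sigma2_e_samples=None,
            h_samples=np.asarray(h_samples),
            summaries={},
        )

    def test_degenerate_summaries(self):
        mean, ci = ph.phylo_heritability(self._fit(np.zeros(100)))
        assert mean == 0.0 and ci == (0.0, 0.0)
        mean, _ = ph.phylo_heritability(self._fit(np.full(100, 0.5)))
        assert mean == pytest.approx(0.5)
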