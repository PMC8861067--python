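import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stopover as st


class TestRinging:
    def test_same_seed_reproduces_records(self):
        cfg = st.SyntheticConfig(seed=7, years_per_island=[5] * 9)
        a = st.simulate_ringing(cfg)
        b = st.simulate_ringing(cfg)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        pd.testing.assert_frame_equal(a[2], b[2])

    def test_matrix_dimensions(self):
        cfg = st.SyntheticConfig(seed=8, years_per_island=[5, 6, 7, 8, 9,
                                                           10, 11, 12, 13])
        captures, _, _ = st.simulate_ringing(cfg)
        cm = st.pivot(captures)
        assert cm.counts.shape == (sum([5, 6, 7, 8, 9, 10, 11, 12, 13]), 35)

    def test_flat_world_columns_match_analytic_mean(self):
        """No effects, no noise: each species' mean across island-years
        should sit within 3 Monte-Carlo SEs of its Poisson mean."""
        cfg = st.SyntheticConfig(
            seed=9, n_area_species=0, n_dsouth_species=0, year_sd=0.0,
            island_sd=0.0, years_per_island=[10] * 9, n_species=10)
        captures, _, truth = st.simulate_ringing(cfg)
        cm = st.pivot(captures)
        mu = truth["abundance"] * cfg.scale * (cfg.net_metres / 100) * cfg.days
        n = len(cm.counts)
        for sp in cm.counts.columns:
            m = cm.counts[sp].mean()
            se = np.sqrt(mu[sp] / n)
            assert abs(m - mu[sp]) <= 3 * se + 1e-9

    def test_area_effect_expected_ratio(self):
        """beta_area = 1 and a 10x area ratio: expected counts scale 10x."""
        desc = pd.DataFrame(
            {"area": [1.0, 10.0], "min_d_south_land": [100.0, 100.0]},
            index=pd.Index(["small", "big"], name="island"))
        cfg = st.SyntheticConfig(
            seed=10, n_islands=2, n_species=1, n_area_species=1,
            n_dsouth_species=0, beta_area=1.0, year_sd=0.0, island_sd=0.0,
            years_per_island=[2, 2])
        _, _, truth = st.simulate_ringing(cfg, desc)
        mu = st.expected_counts(cfg, truth, desc)
        assert mu.loc["big"].iloc[0] / mu.loc["small"].iloc[0] == \
            pytest.approx(10.0)

    def test_dsouth_monotone_in_expectation(self, island_table):
        cfg = st.SyntheticConfig(seed=11)
        _, _, truth = st.simulate_ringing(cfg)
        mu = st.expected_counts(cfg, truth, island_table)
        responder = truth.index[truth["beta_dsouth"] > 0][0]
        ordering = island_table["min_d_south_land"].sort_values().index
        assert mu.loc[ordering, responder].is_monotonic_increasing

    def test_nbinom2_variance_structure(self):
        cfg = st.SyntheticConfig(
            seed=12, n_species=1, n_area_species=0, n_dsouth_species=0,
            year_sd=0.0, island_sd=0.0, family="nbinom2", theta=2.0,
            years_per_island=[16] * 9)
        rng = np.random.default_rng(0)
        # direct check of the sampling family at a fixed mu
        mu, theta, n = 50.0, cfg.theta, 200_000
        draws = rng.negative_binomial(theta, theta / (theta + mu), size=n)
        expected_var = mu + mu**2 / theta
        assert draws.var() == pytest.approx(expected_var, rel=0.05)
        captures, _, _ = st.simulate_ringing(cfg)
        assert (captures["count"] >= 0).all()

    def test_nonpositive_descriptor_rejected(self):
        desc = pd.DataFrame({"area": [0.0, 1.0],
                             "min_d_south_land": [5.0, 5.0]},
                            index=pd.Index(["zero", "ok"], name="island"))
        cfg = st.SyntheticConfig(seed=1, n_islands=2, n_species=2,
                                 n_area_species=0, n_dsouth_species=0,
                                 years_per_island=[2, 2])
        with pytest.raises(ValueError, match="zero"):
            st.simulate_ringing(cfg, desc)


class TestTraits:
    def test_no_linkage_gives_independence(self):
        cfg = st.SyntheticConfig(seed=13, kipp_area_slope=0.0,
                                 kipp_dsouth_slope=0.0)
        _, _, truth = st.simulate_ringing(cfg)
        traits = st.simulate_traits(cfg, truth)
        r, p = stats.pearsonr(traits["kipp_mean"], truth["beta_area"])
        assert abs(r) < 0.4  # within sampling error of zero at n = 35

    def test_noiseless_linkage_perfect_rank_correlation(self):
        cfg = st.SyntheticConfig(seed=14, kipp_noise_sd=0.0,
                                 kipp_dsouth_slope=0.0,
                                 beta_area_values=np.linspace(0, 1, 35))
        _, _, truth = st.simulate_ringing(cfg)
        traits = st.simulate_traits(cfg, truth)
        rho, _ = stats.spearmanr(traits["kipp_mean"], truth["beta_area"])
        assert rho == pytest.approx(1.0)

    def test_default_kipp_war_strongly_correlated(self):
        cfg = st.SyntheticConfig(seed=15)
        _, _, truth = st.simulate_ringing(cfg)
        traits = st.simulate_traits(cfg, truth)
        r, _ = stats.pearsonr(traits["kipp_mean"], traits["wing_aspect_ratio"])
        assert r > 0.8


class TestTree:
    def test_two_tips(self):
        tree = st.simulate_tree(2, seed=0)
        labels = sorted(lf.taxon.label for lf in tree.leaf_nodes())
        assert labels == ["SP01", "SP02"]
        depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
        assert np.allclose(depths, 1.0)

    def test_ultrametric_35_tips(self):
        tree = st.simulate_tree(35, seed=1)
        depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
        assert len(depths) == 35
        assert np.allclose(depths, 1.0, atol=1e-9)

    def test_same_seed_same_topology(self):
        a = st.simulate_tree(10, seed=2).as_string(schema="newick")
        b = st.simulate_tree(10, seed=2).as_string(schema="newick")
        assert a == b


class TestTraitOnTree:
    def test_sigma_zero_constant(self):
        tree = st.simulate_tree(8, seed=3)
        vals = st.simulate_trait_on_tree(tree, 1.0, 0.0, seed=0, root_value=5.0)
        assert np.allclose(vals, 5.0)

    def test_lambda_zero_uncorrelated_tips(self):
        tree = st.simulate_tree(4, seed=4)
        draws = np.array([
            st.simulate_trait_on_tree(tree, 0.0, 1.0, seed=s).to_numpy()
            for s in range(400)])
        corr = np.corrcoef(draws.T)
        off = corr[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.2

    def test_sister_tips_highly_correlated_under_bm(self):
        tree = st.parse_newick("((A:0.01,B:0.01):0.99,C:1);")
        draws = np.array([
            st.simulate_trait_on_tree(tree, 1.0, 1.0, seed=s).to_numpy()
            for s in range(400)])
        cov = st.phylo_cov(tree)
        ia, ib = cov.taxa.index("A"), cov.taxa.index("B")
        r = np.corrcoef(draws[:, ia], draws[:, ib])[0, 1]
        assert r > 0.95  # closed-form BM correlation is 0.99
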