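import numpy as np
import pandas as pd
import pytest

import stopover as st
from conftest import make_tm
from stopover.io import GEOGRAPHIC_VARS, HABITAT_VARS
from stopover.ordination import (expand_to_samples, partial_rda_test,
                                 prepare_predictors)


def naive_rda_eigenvalues(Y, X):
    """Independent oracle: least squares by normal equations, then
    eigendecomposition of the fitted-value covariance."""
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    Xs = Xc / Xc.std(axis=0, ddof=1)
    B = np.linalg.solve(Xs.T @ Xs, Xs.T @ Yc)
    F = Xs @ B
    cov = F.T @ F / (len(Y) - 1)
    eig = np.linalg.eigvalsh(cov)[::-1]
    return eig[eig > 1e-12 * max(eig.max(), 1)]


@pytest.fixture
def sample_pred():
    tm = make_tm(n_islands=5, years=3, n_species=6, seed=2)
    rng = np.random.default_rng(3)
    pred = pd.DataFrame(rng.normal(size=(5, 3)), columns=list("uvw"),
                        index=[f"I{i+1}" for i in range(5)])
    return tm, expand_to_samples(pred, tm.values.index)


class TestVif:
    def test_orthogonal_predictors_unit_vif(self):
        rng = np.random.default_rng(8)
        Q, _ = np.linalg.qr(rng.normal(size=(12, 3)))
        X = pd.DataFrame(Q, columns=list("abc"))
        v = st.vif(X)
        kept, trace = st.vif_filter(X, threshold=10)
        assert trace == []
        assert np.allclose(v, 1.0, atol=0.2)

    def test_constructed_collinearity_removes_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = rng.normal(size=40)
        X = pd.DataFrame({"x": x, "y": y,
                          "z": x + y + rng.normal(0, 1e-3, 40)})
        kept, trace = st.vif_filter(X, threshold=10)
        assert len(trace) == 1
        assert (st.vif(kept) < 10).all()

    def test_real_geographic_set_removals(self, island_table):
        """The printed geographic descriptors: iterative VIF removal drops
        minimum distance to Africa and latitude, leaving max VIF near 2."""
        geo = prepare_predictors(island_table, GEOGRAPHIC_VARS)
        kept, trace = st.vif_filter(geo, threshold=10.0)
        removed = {name for name, _ in trace}
        assert removed == {"min_dist_africa", "latitude"}
        assert st.vif(kept).max() <= 2.1 * 1.1

    def test_real_habitat_set_all_below_three(self, island_table):
        hab = prepare_predictors(island_table, HABITAT_VARS)
        assert (st.vif(hab) < 3).all()

    def test_constant_column_rejected(self):
        X = pd.DataFrame({"a": [1.0, 1, 1], "b": [1.0, 2, 3]})
        with pytest.raises(ValueError, match="constant"):
            st.vif_filter(X)


class TestRda:
    def test_ezekiel_formula(self):
        assert st.ezekiel_adjust(0.5, 11, 2) == pytest.approx(0.375)

    def test_exact_linear_response(self):
        rng = np.random.default_rng(1)
        n = 20
        pred = pd.DataFrame(rng.normal(size=(n, 2)), columns=["p1", "p2"])
        Y = pd.DataFrame(
            pred.to_numpy() @ rng.normal(size=(2, 5)),
            index=pd.MultiIndex.from_tuples(
                [(f"I{i % 4}", i) for i in range(n)]),
            columns=[f"S{j}" for j in range(5)])
        pred.index = Y.index
        rr = st.rda(Y, pred)
        assert rr.r2 == pytest.approx(1.0, abs=1e-10)
        assert rr.n_axes == 2

    def test_oracle_equivalence(self, sample_pred):
        tm, pred = sample_pred
        rr = st.rda(tm, pred)
        eig_oracle = naive_rda_eigenvalues(tm.values.to_numpy(),
                                           pred.to_numpy())
        assert np.allclose(rr.eigenvalues, eig_oracle, atol=1e-8)
        assert (np.diff(rr.eigenvalues) <= 1e-12).all()

    def test_predictor_rotation_invariance(self, sample_pred):
        tm, pred = sample_pred
        rng = np.random.default_rng(9)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        mixed = pd.DataFrame(pred.to_numpy() @ Q, index=pred.index,
                             columns=list("abc"))
        r1, r2 = st.rda(tm, pred), st.rda(tm, mixed)
        assert np.allclose(r1.eigenvalues, r2.eigenvalues, atol=1e-9)
        assert r1.r2 == pytest.approx(r2.r2, abs=1e-10)

    def test_axis_percentages_sum_to_r2(self, sample_pred):
        tm, pred = sample_pred
        rr = st.rda(tm, pred)
        assert rr.prop_total.sum() == pytest.approx(100 * rr.r2, abs=1e-9)
        assert rr.prop_total.sum() <= 100 + 1e-9

    def test_rank_deficiency_reported(self, sample_pred):
        tm, pred = sample_pred
        pred = pred.assign(dup=pred["u"])
        with pytest.raises(ValueError, match="rank"):
            st.rda(tm, pred)

    def test_null_predictors_give_uniform_axis_p(self):
        rng = np.random.default_rng(11)
        ps = []
        for rep in range(60):
            Y = pd.DataFrame(rng.normal(size=(18, 4)))
            pred = pd.DataFrame(rng.normal(size=(18, 2)), columns=["a", "b"])
            rr = st.rda(Y, pred, n_perm=49, seed=rep)
            ps.append(rr.axis_p[0])
        ps = np.array(ps)
        assert 0.2 < ps.mean() < 0.8
        assert (ps <= 0.1).mean() < 0.35


class TestForwardSelection:
    def test_empty_predictor_set(self):
        tm = make_tm(seed=1)
        assert st.forward_select(tm, pd.DataFrame(index=tm.values.index)) == []

    def test_informative_predictor_selected_first(self):
        rng = np.random.default_rng(2)
        hits = 0
        for rep in range(20):
            x = rng.normal(size=30)
            Y = pd.DataFrame(np.outer(x, rng.normal(size=4))
                             + rng.normal(0, 0.3, size=(30, 4)))
            pred = pd.DataFrame({"signal": x,
                                 "noise1": rng.normal(size=30),
                                 "noise2": rng.normal(size=30)})
            sel = st.forward_select(Y, pred, n_perm=99, seed=rep)
            if sel and sel[0] == "signal":
                hits += 1
        assert hits >= 19

    def test_all_noise_rarely_selects(self):
        rng = np.random.default_rng(3)
        any_selected = 0
        for rep in range(40):
            Y = pd.DataFrame(rng.normal(size=(20, 4)))
            pred = pd.DataFrame(rng.normal(size=(20, 3)), columns=list("abc"))
            sel = st.forward_select(Y, pred, n_perm=99, seed=rep,
                                    adjr2_stop=False)
            any_selected += bool(sel)
        assert any_selected / 40 < 0.3  # greedy inflation stays modest


class TestVarpart:
    def test_duplicate_blocks_all_shared(self, sample_pred):
        tm, pred = sample_pred
        vp = st.varpart2(tm, pred, pred.copy())
        assert abs(vp.geo_unique) < 1e-10
        assert abs(vp.hab_unique) < 1e-10
        assert vp.shared == pytest.approx(vp.r2_adj_all, abs=1e-10)

    def test_disjoint_blocks_no_shared_fraction(self):
        rng = np.random.default_rng(4)
        n = 40
        x1 = pd.DataFrame({"a": rng.normal(size=n)})
        x2 = pd.DataFrame({"b": rng.normal(size=n)})
        Y = pd.DataFrame(np.column_stack([
            x1["a"] + rng.normal(0, 0.05, n),
            x2["b"] + rng.normal(0, 0.05, n)]))
        vp = st.varpart2(Y, x1, x2)
        assert abs(vp.shared) < 0.05
        assert vp.geo_unique == pytest.approx(vp.r2_adj_geo, abs=0.05)

    def test_additivity_identity(self, sample_pred):
        tm, pred = sample_pred
        vp = st.varpart2(tm, pred[["u"]], pred[["v", "w"]])
        total = vp.geo_unique + vp.shared + vp.hab_unique
        assert total == pytest.approx(vp.r2_adj_all, abs=1e-10)

    def test_unique_fraction_testable(self, sample_pred):
        tm, pred = sample_pred
        out = partial_rda_test(tm, pred[["u"]], pred[["v", "w"]],
                               n_perm=99, seed=0)
        assert 0 < out["p"] <= 1
        assert out["F"] >= 0


class TestAxisAssociations:
    def test_species_loading_on_single_axis(self):
        rng = np.random.default_rng(5)
        scores = rng.normal(size=20)
        Y = pd.DataFrame({
            "loaded": 2 * scores,
            "other": rng.normal(size=20),
        }, index=pd.MultiIndex.from_tuples([(f"I{i % 4}", i) for i in range(20)]))
        pred = pd.DataFrame({"p": scores}, index=Y.index)
        rr = st.rda(Y, pred)
        corr = st.species_axis_correlations(rr, Y, n_axes=1)
        assert abs(corr.loc["loaded", "RDA1_r"]) > 0.99
        assert corr.loc["loaded", "RDA1_p_bonf"] <= 1.0

    def test_bonferroni_capped_at_one(self):
        tm = make_tm(seed=6)
        pred = expand_to_samples(
            pd.DataFrame({"x": np.arange(4.0)},
                         index=[f"I{i+1}" for i in range(4)]),
            tm.values.index)
        rr = st.rda(tm, pred)
        corr = st.species_axis_correlations(rr, tm, n_axes=1)
        assert (corr["RDA1_p_bonf"].dropna() <= 1.0).all()

    def test_island_level_p_guards_against_pseudoreplication(self):
        """Axis scores with island-level structure unrelated to an
        island-constant descriptor: treating the 30 samples as independent
        inflates significance, the island-mean regression stays honest."""
        from scipy import stats as sps

        from stopover.ordination import RdaResult

        rng = np.random.default_rng(7)
        ps_island, ps_naive = [], []
        for rep in range(200):
            n_isl, per = 6, 5
            idx = pd.MultiIndex.from_tuples(
                [(f"I{i}", k) for i in range(n_isl) for k in range(per)])
            # strong island-level random structure in the axis scores
            island_effect = np.repeat(rng.normal(size=n_isl), per)
            scores = island_effect + 0.2 * rng.normal(size=n_isl * per)
            rr = RdaResult(
                eigenvalues=np.array([1.0]), prop_total=np.array([100.0]),
                prop_constrained=np.array([100.0]),
                site_scores=pd.DataFrame({"RDA1": scores}, index=idx),
                species_scores=pd.DataFrame(), biplot_scores=pd.DataFrame(),
                axis_p=None, r2=1.0, r2_adj=1.0, n=n_isl * per, m=1)
            pred_island = pd.DataFrame({"x": rng.normal(size=n_isl)},
                                       index=[f"I{i}" for i in range(n_isl)])
            pred = expand_to_samples(pred_island, idx)
            tab = st.axis_variable_association(rr, pred, n_axes=1)
            ps_island.append(tab["p_island"].iloc[0])
            ps_naive.append(sps.pearsonr(pred["x"], scores)[1])
        ps_island, ps_naive = np.array(ps_island), np.array(ps_naive)
        assert (ps_island < 0.05).mean() < 0.12      # honest size
        assert (ps_naive < 0.05).mean() > 0.2        # naive is inflated
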