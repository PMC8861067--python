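import numpy as np
import pandas as pd
import pytest

import stopover as st
from conftest import make_tm


def brute_force_partition(tm):
    """Naive triple-loop computation of every sum of squares."""
    values = tm.values
    islands = list(dict.fromkeys(values.index.get_level_values(0)))
    species = list(values.columns)
    ybar_j = {j: values[j].mean() for j in species}
    ybar_ij = {(i, j): values.loc[i, j].mean() for i in islands for j in species}
    ss_total = ss_temp = 0.0
    ss_island = 0.0
    ss_temp_i = {i: 0.0 for i in islands}
    weighted = 0.0
    for i in islands:
        block = values.loc[i]
        for j in species:
            ss_island += (ybar_ij[i, j] - ybar_j[j]) ** 2
            weighted += len(block) * (ybar_ij[i, j] - ybar_j[j]) ** 2
            for k in range(len(block)):
                y = block[j].iloc[k]
                ss_total += (y - ybar_j[j]) ** 2
                ss_temp += (y - ybar_ij[i, j]) ** 2
                ss_temp_i[i] += (y - ybar_ij[i, j]) ** 2
    return ss_total, ss_island, ss_temp, ss_temp_i, weighted


class TestTotalBeta:
    def test_identical_rows_uniform_with_warning(self, caplog):
        counts = pd.DataFrame(
            [[1, 2], [1, 2]],
            index=pd.MultiIndex.from_tuples([("A", 1), ("A", 2)]))
        tm = st.chord_transform(st.CommunityMatrix(counts))
        ss, bd, lcbd, scbd = st.total_beta(tm)
        assert ss == 0 and bd == 0
        assert np.allclose(lcbd, 0.5) and np.allclose(scbd, 0.5)

    def test_orthogonal_two_rows_hand_computed(self):
        counts = pd.DataFrame(
            [[1, 0], [0, 1]],
            index=pd.MultiIndex.from_tuples([("A", 1), ("B", 1)]))
        tm = st.chord_transform(st.CommunityMatrix(counts))
        ss, bd, lcbd, scbd = st.total_beta(tm)
        assert np.isclose(ss, 1.0)
        assert np.isclose(bd, 1.0)
        assert np.allclose(lcbd, [0.5, 0.5])
        assert np.allclose(scbd, [0.5, 0.5])

    def test_contributions_sum_to_one(self):
        tm = make_tm(seed=5)
        _, _, lcbd, scbd = st.total_beta(tm)
        assert np.isclose(lcbd.sum(), 1.0, atol=1e-10)
        assert np.isclose(scbd.sum(), 1.0, atol=1e-10)

    def test_single_sample_rejected(self):
        counts = pd.DataFrame([[1, 2]],
                              index=pd.MultiIndex.from_tuples([("A", 1)]))
        cm = st.CommunityMatrix(counts)
        tm = st.chord_transform(cm)
        with pytest.raises(ValueError):
            st.total_beta(tm)


class TestPartition:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        years = list(rng.integers(2, 6, size=4))
        tm = make_tm(n_islands=4, years=years, n_species=5, seed=seed + 100)
        part = st.partition_beta(tm)
        ss_total, ss_island, ss_temp, ss_temp_i, weighted = \
            brute_force_partition(tm)
        assert np.isclose(part.ss_total, ss_total, atol=1e-10)
        assert np.isclose(part.ss_island, ss_island, atol=1e-10)
        assert np.isclose(part.ss_temp, ss_temp, atol=1e-10)
        for isl, v in ss_temp_i.items():
            assert np.isclose(part.ss_temp_island[isl], v, atol=1e-10)
        # exact ANOVA decomposition
        assert abs(ss_total - ss_temp - weighted) < 1e-10
        assert abs(part.identity_residual) < 1e-10

    def test_temporally_constant_islands(self):
        counts = pd.DataFrame(
            [[3, 4], [3, 4], [1, 1], [1, 1]],
            index=pd.MultiIndex.from_tuples(
                [("A", 1), ("A", 2), ("B", 1), ("B", 2)]))
        part = st.partition_beta(st.chord_transform(st.CommunityMatrix(counts)))
        assert np.isclose(part.ss_temp, 0.0, atol=1e-14)
        assert np.allclose(part.bd_temp_island, 0.0, atol=1e-14)
        # all variance is between islands: SS_total = sum_i Y_i * between term
        assert np.isclose(part.ss_total, 2 * part.ss_island, atol=1e-12)

    def test_balanced_design_island_ss_relation(self):
        q = 3
        tm = make_tm(n_islands=4, years=q, seed=9)
        part = st.partition_beta(tm)
        weighted = part.ss_total - part.ss_temp
        assert np.isclose(part.ss_island, weighted / q, atol=1e-10)

    def test_single_island_rejected(self):
        tm = make_tm(n_islands=1, years=4, seed=2)
        with pytest.raises(ValueError, match="islands"):
            st.partition_beta(tm)

    def test_single_year_island_excluded_from_bdti(self):
        tm = make_tm(n_islands=3, years=[1, 3, 3], seed=4)
        part = st.partition_beta(tm)
        assert "I1" not in part.bd_temp_island.index
        assert "I1" in part.lcbd.index.get_level_values(0)
        assert np.isclose(part.lcbd.sum(), 1.0)

    def test_bd_total_from_distance_formulation(self):
        """Variance formulation equals the Gower-centered distance one."""
        from scipy.spatial.distance import pdist
        tm = make_tm(seed=7)
        part = st.partition_beta(tm)
        n = part.n_samples
        ss_from_d = (pdist(tm.values.to_numpy())**2).sum() / n
        assert np.isclose(part.ss_total, ss_from_d, atol=1e-10)

    def test_duplicate_sample_has_equal_lcbd(self):
        tm = make_tm(seed=8)
        counts = (tm.values * 100).round().astype(int)
        dup = pd.concat([counts, counts.iloc[[0]].rename(
            index={counts.index[0][1]: 2099}, level=1)])
        tm2 = st.chord_transform(st.CommunityMatrix(dup))
        _, _, lcbd, _ = st.total_beta(tm2)
        assert np.isclose(lcbd.iloc[0], lcbd.iloc[-1], atol=1e-12)


class TestIslandComparisons:
    def test_published_island_summaries_correlate(self, island_table):
        r, p = st.correlation(island_table["lcbd"], island_table["bd_ti"])
        assert abs(r - 0.912) < 0.01
        assert p < 0.001

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            st.correlation([1, 1, 1], [1, 2, 3])

    def test_anova_on_log_lcbd(self, synthetic_tm):
        part = st.partition_beta(synthetic_tm)
        f, df_b, df_w, p, tukey = st.island_temporal_tests(part)
        assert df_b == part.n_islands - 1
        assert df_w == part.n_samples - part.n_islands
        assert f >= 0 and 0 <= p <= 1
        assert len(tukey) == part.n_islands * (part.n_islands - 1) // 2

    def test_anova_type_i_error_under_null(self):
        """Exchangeable log-LCBD across islands: rejection near alpha."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_sims = 400
        for _ in range(n_sims):
            counts = pd.DataFrame(
                rng.integers(1, 60, size=(20, 5)),
                index=pd.MultiIndex.from_tuples(
                    [(f"I{i}", 2000 + k) for i in range(4) for k in range(5)]))
            part = st.partition_beta(
                st.chord_transform(st.CommunityMatrix(counts)))
            _, _, _, p, _ = st.island_temporal_tests(part)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_sims <= 0.09
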