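"""Beta diversity as the total variance of the community matrix, partitioned
into between-island and within-island (temporal) components.

With chord-transformed data the total beta diversity BD_total lies in
[0, 1]. Writing y_ijk for the transformed abundance of species j on island i
in year k, ybar_ij for its island mean over years and ybar_j for its grand
mean:

    SS_total  = sum_ijk (y_ijk - ybar_j)^2        BD_I,T = SS_total/(N-1)
    SS_I      = sum_ij  (ybar_ij - ybar_j)^2      BD_I   = SS_I/(n-1)
    SS_temp   = sum_ijk (y_ijk - ybar_ij)^2       BD_T   = SS_temp/(Y-n)
    SS_temp,i = sum_jk  (y_ijk - ybar_ij)^2       BD_Ti  = SS_temp,i/(Y_i-1)

where N = Y = total island-year samples, n = islands, Y_i = years on island
i. The exact ANOVA decomposition SS_total = SS_temp +
sum_i Y_i sum_j (ybar_ij - ybar_j)^2 always holds and is returned as a
self-check residual.

LCBD_r = SS_r / SS_total (row contributions) and SCBD_j = SS_j / SS_total
(species/column contributions); each set sums to 1.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .transforms import TransformedMatrix

logger = logging.getLogger("stopover")


@dataclasses.dataclass
class BetaPartitionResult:
    ss_total: float
    bd_total: float                 # BD_I,T
    ss_island: float                # SS_I
    bd_island: float                # BD_I
    ss_temp: float
    bd_temp: float                  # BD_T
    ss_temp_island: pd.Series       # SS_temp,i per island
    bd_temp_island: pd.Series       # BD_Ti per island
    lcbd: pd.Series                 # per island-year sample
    lcbd_island_mean: pd.Series     # raw-scale mean of yearly LCBD per island
    lcbd_island_logmean: pd.Series  # mean of log(LCBD) per island
    scbd: pd.Series                 # per species
    n_samples: int                  # N (= Y)
    n_islands: int
    years_per_island: pd.Series     # Y_i
    identity_residual: float        # SS_total - SS_temp - sum_i Y_i sum_j (ybar_ij-ybar_j)^2

    def summary(self) -> pd.DataFrame:
        """Per-island table: years, BD_Ti, mean LCBD (Table-style output)."""
        return pd.DataFrame({
            "years": self.years_per_island,
            "bd_ti": self.bd_temp_island,
            "mean_lcbd": self.lcbd_island_mean,
        })


def total_beta(tm: TransformedMatrix):
    """Total beta diversity with local and species contributions.

    Returns (SS_total, BD_total, LCBD, SCBD). If the matrix has no variance
    at all, LCBD and SCBD are reported as uniform with a warning rather than
    as NaN, preserving their sum-to-one contract.
    """
    Y = tm.values
    N = len(Y)
    if N < 2:
        raise ValueError("total beta diversity needs at least 2 samples")
    centered = Y - tm.species_means
    sq = centered**2
    ss_total = float(sq.values.sum())
    bd_total = ss_total / (N - 1)
    if ss_total == 0:
        logger.warning("total_beta: matrix has zero variance; "
                       "reporting uniform LCBD/SCBD")
        lcbd = pd.Series(1.0 / N, index=Y.index, name="lcbd")
        scbd = pd.Series(1.0 / Y.shape[1], index=Y.columns, name="scbd")
    else:
        lcbd = (sq.sum(axis=1) / ss_total).rename("lcbd")
        scbd = (sq.sum(axis=0) / ss_total).rename("scbd")
    return ss_total, bd_total, lcbd, scbd


def partition_beta(tm: TransformedMatrix) -> BetaPartitionResult:
    """Partition total beta diversity into island and temporal components."""
    Y = tm.values
    N = len(Y)
    n = len(tm.islands)
    if n < 2:
        raise ValueError("beta partition needs >=2 islands")
    ss_total, bd_total, lcbd, scbd = total_beta(tm)

    yi = tm.years_per_island()
    dev_island = tm.island_means - tm.species_means
    ss_island = float((dev_island**2).values.sum())
    bd_island = ss_island / (n - 1)

    within = Y - tm.island_means.reindex(Y.index.get_level_values(0)).values
    ss_temp_island = (within**2).sum(axis=1).groupby(level=0, sort=False).sum()
    ss_temp = float(ss_temp_island.sum())
    if N - n <= 0:
        raise ValueError("BD_T undefined: total samples must exceed islands")
    bd_temp = ss_temp / (N - n)

    single = yi[yi < 2].index
    if len(single):
        logger.warning("partition_beta: island(s) with a single year excluded "
                       "from BD_Ti: %s", list(single))
    bd_temp_island = (ss_temp_island / (yi - 1)).drop(index=single)

    # exact decomposition check: SS_total = SS_temp + sum_i Y_i sum_j (.)^2
    weighted_between = float(((dev_island**2).sum(axis=1) * yi).sum())
    residual = ss_total - ss_temp - weighted_between

    lcbd_raw = lcbd.groupby(level=0, sort=False).mean()
    with np.errstate(divide="ignore"):
        lcbd_log = np.log(lcbd).groupby(level=0, sort=False).mean()

    return BetaPartitionResult(
        ss_total=ss_total, bd_total=bd_total,
        ss_island=ss_island, bd_island=bd_island,
        ss_temp=ss_temp, bd_temp=bd_temp,
        ss_temp_island=ss_temp_island.rename("ss_temp_i"),
        bd_temp_island=bd_temp_island.rename("bd_ti"),
        lcbd=lcbd, lcbd_island_mean=lcbd_raw.rename("mean_lcbd"),
        lcbd_island_logmean=lcbd_log.rename("mean_log_lcbd"),
        scbd=scbd, n_samples=N, n_islands=n,
        years_per_island=yi.rename("years"),
        identity_residual=float(residual),
    )


def correlation(x, y, method: str = "pearson"):
    """Pearson or Spearman correlation with a two-sided t-approximation p.

    Raises on constant input, where the correlation is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for a constant vector")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
    elif method == "spearman":
        r, p = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r), float(p)


def island_temporal_tests(result: BetaPartitionResult, alpha: float = 0.05):
    """Compare yearly LCBD between islands.

    Yearly LCBD values are log-transformed (their distribution is right
    skewed) and compared with a one-way ANOVA across islands followed by a
    Tukey HSD post-hoc test. Returns (F, df_between, df_within, p, tukey
    table).
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    lcbd = result.lcbd
    islands = lcbd.index.get_level_values(0)
    groups = [np.log(lcbd[islands == isl].values) for isl in result.lcbd_island_mean.index]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >=2 islands with >=2 years each")
    f_stat, p = stats.f_oneway(*groups)
    df_b = result.n_islands - 1
    df_w = result.n_samples - result.n_islands
    tukey = pairwise_tukeyhsd(np.log(lcbd.values), np.asarray(islands), alpha=alpha)
    tukey_df = pd.DataFrame(tukey.summary().data[1:],
                            columns=tukey.summary().data[0])
    return float(f_stat), df_b, df_w, float(p), tukey_df
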