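"""Does continental abundance drive stopover abundance?

Log-log linear models of island-level mean numbers ringed on species'
continental abundance, with island main effect and interaction, compared by
AICc; plus the single pooled regression of species totals on continental
abundance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .transforms import CommunityMatrix

logger = logging.getLogger("stopover")


def aicc(aic: float, k: int, n: int) -> float:
    """Small-sample AIC correction: AIC + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        raise ValueError("AICc undefined: n must exceed k + 1")
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def island_species_means(cm: CommunityMatrix) -> pd.DataFrame:
    """Mean number ringed per year, per island x species."""
    return cm.counts.groupby(level=0, sort=False).mean()


def species_totals(cm: CommunityMatrix) -> pd.Series:
    """Total number ringed per species over all islands and years."""
    return cm.counts.sum(axis=0)


_CANDIDATES = {
    "abundance_x_island": "log_mean ~ log_abund * C(island)",
    "abundance_plus_island": "log_mean ~ log_abund + C(island)",
    "abundance_only": "log_mean ~ log_abund",
    "island_only": "log_mean ~ C(island)",
    "null": "log_mean ~ 1",
}


def fit_loglog_models(mean_ringed: pd.DataFrame, abundance: pd.Series
                      ) -> pd.DataFrame:
    """AICc comparison of island/abundance models for mean numbers ringed.

    ``mean_ringed``: island x species table of per-year means. Rows with a
    zero mean (species never ringed on that island) are omitted — the
    log is undefined and the species is simply absent there.

    Returns one row per candidate model with k (parameters including the
    error variance), log-likelihood, AICc and delta AICc vs the best model.
    """
    long = mean_ringed.stack().rename("mean_ringed").reset_index()
    long.columns = ["island", "species", "mean_ringed"]
    zero = long["mean_ringed"] <= 0
    if zero.any():
        logger.info("fit_loglog_models: omitting %d island-species rows with "
                    "zero mean", int(zero.sum()))
        long = long[~zero]
    long["log_mean"] = np.log(long["mean_ringed"])
    long["log_abund"] = np.log(abundance.reindex(long["species"]).values)
    if long["log_abund"].isna().any():
        missing = sorted(long.loc[long["log_abund"].isna(), "species"].unique())
        raise ValueError(f"no continental abundance for species: {missing}")
    n = len(long)
    rows = []
    for name, formula in _CANDIDATES.items():
        fit = smf.ols(formula, data=long).fit()
        k = int(fit.df_model) + 2  # + intercept + error variance
        if n <= k + 1:
            logger.warning("fit_loglog_models: skipping %s (n=%d <= k+1=%d)",
                           name, n, k + 1)
            continue
        rows.append({"model": name, "k": k, "loglik": float(fit.llf),
                     "aicc": aicc(float(fit.aic), k, n)})
    out = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    out["delta_aicc"] = out["aicc"] - out["aicc"].min()
    return out


def fit_final_regression(totals: pd.Series, abundance: pd.Series) -> dict:
    """OLS of log10 total ringed on log10 continental abundance.

    Returns slope, intercept, F with (1, n-2) df, p, Pearson r, and the
    species flagged as influential on the slope (|standardized DFBETA| >
    2/sqrt(n)).
    """
    common = totals.index.intersection(abundance.index)
    y = np.log10(totals.reindex(common).astype(float))
    x = np.log10(abundance.reindex(common).astype(float))
    ok = np.isfinite(y) & np.isfinite(x)
    y, x = y[ok], x[ok]
    n = len(y)
    if n < 3:
        raise ValueError("final regression needs >=3 species")
    X = sm.add_constant(x.to_numpy())
    fit = sm.OLS(y.to_numpy(), X).fit()
    dfbetas = fit.get_influence().dfbetas[:, 1]
    flagged = list(y.index[np.abs(dfbetas) > 2.0 / np.sqrt(n)])
    r, _ = stats.pearsonr(x, y)
    return {
        "slope": float(fit.params[1]),
        "intercept": float(fit.params[0]),
        "F": float(fit.fvalue),
        "df": (1, n - 2),
        "p": float(fit.f_pvalue),
        "r": float(r),
        "n": n,
        "influential": flagged,
    }
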