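"""Per-species count models of abundance against island descriptors.

Each species' island-year counts are modeled with a log link and an offset
converting counts to rates: either the log total number ringed in that
island-year (percentage-of-captures mode) or the log of hundreds of
net-metres times ringing days (captures-per-effort mode; islands with
non-comparable net placement are excluded there). Year enters as a fixed
factor absorbing passage-intensity differences between springs; island
descriptors are island-constant, so no island factor can sit beside them
(it would absorb them completely) — see the methods note for how this
replaces the original random-intercept formulation.

Families: Poisson, nbinom1 (variance linear in the mean) and nbinom2
(variance quadratic in the mean). The family is chosen on null-model AICc,
then linear and quadratic models in each descriptor are retained if they
beat the null's AICc; a quadratic is kept over the linear only if the
likelihood-ratio test favors it at p < 0.05.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .abundance import aicc
from .ordination import prepare_predictors
from .transforms import CommunityMatrix

logger = logging.getLogger("stopover")

FAMILIES = ("poisson", "nbinom1", "nbinom2")


@dataclasses.dataclass
class GlmFit:
    family: str
    params: pd.Series
    bse: pd.Series
    theta: float | None       # nbinom2 size parameter (variance mu + mu^2/theta)
    alpha: float | None       # raw dispersion parameter as estimated
    loglik: float
    aicc: float
    n: int
    k: int
    converged: bool
    poisson_like: bool = False  # dispersion collapsed toward 0


def build_offsets(cm: CommunityMatrix, effort: pd.DataFrame | None = None,
                  mode: str = "percentage",
                  excluded_islands: tuple[str, ...] = ()) -> pd.Series:
    """Log offset per island-year row.

    percentage mode: ln(total ringed of the selected species that
    island-year). rate mode: ln(hundreds of net-metres x ringing days),
    with ``excluded_islands`` rows absent entirely.
    """
    if mode == "percentage":
        totals = cm.counts.sum(axis=1)
        zero = totals <= 0
        if zero.any():
            logger.warning("build_offsets: dropping %d island-years with zero "
                           "total ringed", int(zero.sum()))
            totals = totals[~zero]
        return np.log(totals.astype(float)).rename("offset")
    if mode == "rate":
        if effort is None:
            raise ValueError("rate mode requires effort records")
        eff = effort.copy()
        eff["year"] = eff["date"].dt.year
        per = eff.groupby(["island", "year"]).agg(
            days=("date", "nunique"), net=("net_length", "mean"))
        units = (per["net"] / 100.0) * per["days"]
        if (units <= 0).any():
            logger.warning("build_offsets: dropping island-years with zero effort")
            units = units[units > 0]
        offs = np.log(units).rename("offset")
        offs = offs[~offs.index.get_level_values(0).isin(excluded_islands)]
        return offs.reindex(cm.counts.index.intersection(offs.index))
    raise ValueError(f"unknown offset mode {mode!r}")


def _check_design(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")


def fit_glm(y, X, offset=None, family: str = "poisson",
            maxiter: int = 100) -> GlmFit:
    """Maximum-likelihood count GLM with log link and optional offset.

    ``X`` must already contain its intercept column. AICc parameter counts:
    Poisson k = p; negative-binomial families k = p + 1 for the dispersion.
    """
    y = np.asarray(y)
    if (y < 0).any() or not np.allclose(y, np.round(y)):
        raise ValueError("counts must be non-negative integers")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{i}" for i in range(np.asarray(X).shape[1])]
    X = np.asarray(X, dtype=float)
    _check_design(X)
    offset = None if offset is None else np.asarray(offset, dtype=float)
    n, p = X.shape

    if family == "poisson":
        fit = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset
                     ).fit(maxiter=maxiter)
        if not fit.converged:
            raise RuntimeError("Poisson IRLS failed to converge "
                               f"in {maxiter} iterations")
        k = p
        return GlmFit("poisson", pd.Series(fit.params, index=names),
                      pd.Series(fit.bse, index=names), None, None,
                      float(fit.llf), aicc(-2 * float(fit.llf) + 2 * k, k, n),
                      n, k, True)

    if family not in ("nbinom1", "nbinom2"):
        raise ValueError(f"unknown family {family!r}")

    from statsmodels.discrete.discrete_model import NegativeBinomial

    start = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset
                   ).fit(maxiter=maxiter).params
    loglike_method = "nb1" if family == "nbinom1" else "nb2"
    model = NegativeBinomial(y, X, loglike_method=loglike_method, offset=offset)
    with np.errstate(all="ignore"):
        fit = model.fit(start_params=np.append(start, 0.1), maxiter=maxiter,
                        disp=0, warn_convergence=False)
    if not fit.mle_retvals.get("converged", False):
        # one retry from a gentler start before giving up
        with np.errstate(all="ignore"):
            fit = model.fit(start_params=np.append(start * 0.9, 0.5),
                            maxiter=maxiter, disp=0, warn_convergence=False)
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError(f"{family} ML failed to converge in "
                               f"{maxiter} iterations: {fit.mle_retvals}")
    alpha = float(fit.params[-1])
    poisson_like = alpha < 1e-6
    theta = np.inf if alpha <= 0 else 1.0 / alpha
    k = p + 1
    return GlmFit(family, pd.Series(fit.params[:-1], index=names),
                  pd.Series(fit.bse[:-1], index=names),
                  theta if family == "nbinom2" else None, alpha,
                  float(fit.llf), aicc(-2 * float(fit.llf) + 2 * k, k, n),
                  n, k, True, poisson_like)


def _base_design(index: pd.MultiIndex) -> pd.DataFrame:
    """Intercept plus year fixed-factor dummies (first year as reference)."""
    years = index.get_level_values(1)
    dummies = pd.get_dummies(years, prefix="year", drop_first=True, dtype=float)
    dummies.index = index
    out = pd.concat([pd.Series(1.0, index=index, name="intercept"), dummies],
                    axis=1)
    # drop aliased year dummies (a year seen on a single island-year row set)
    keep = [c for c in out.columns
            if c == "intercept" or out[c].std() > 0]
    return out[keep]


def _choose_family(y, X, offset) -> tuple[str, GlmFit]:
    best = None
    for fam in FAMILIES:
        try:
            fit = fit_glm(y, X, offset, family=fam)
        except (RuntimeError, np.linalg.LinAlgError) as exc:
            logger.info("family %s failed on null model: %s", fam, exc)
            continue
        if best is None or fit.aicc < best[1].aicc:
            best = (fam, fit)
    if best is None:
        raise RuntimeError("no family converged on the null model")
    return best


def _classify_sign(fit: GlmFit, shape: str, x: np.ndarray) -> str:
    if shape == "linear":
        return "+" if fit.params["x"] > 0 else "-"
    a1, a2 = fit.params["x"], fit.params["x2"]
    if a2 != 0:
        x_star = -a1 / (2 * a2)
        if x.min() < x_star < x.max():
            return "intermediate"
    # monotone over the observed range: sign of the derivative at the centre
    return "+" if a1 > 0 else "-"


def select_models(cm: CommunityMatrix, descriptors: pd.DataFrame,
                  variables: list[str], mode: str = "percentage",
                  effort: pd.DataFrame | None = None,
                  excluded_islands: tuple[str, ...] = (),
                  quad_alpha: float = 0.05) -> pd.DataFrame:
    """Model selection per species x descriptor.

    Returns a long table with, per species and variable: the selected
    family, the retained shape (none | linear | quadratic), the effect sign
    (+ / - / intermediate for an interior extremum), AICc values, and
    membership of the species' plausible set (delta AICc <= 2 relative to
    its best retained model).
    """
    offsets = build_offsets(cm, effort, mode, excluded_islands)
    counts = cm.counts.loc[offsets.index]
    base = _base_design(counts.index)
    logx = prepare_predictors(descriptors, variables)
    rows = []
    for sp in counts.columns:
        y = counts[sp].to_numpy()
        if y.sum() == 0:
            logger.warning("select_models: %s has no captures in design; skipped", sp)
            continue
        try:
            family, null_fit = _choose_family(y, base, offsets.to_numpy())
        except RuntimeError as exc:
            logger.warning("select_models: %s null fits failed (%s); skipped",
                           sp, exc)
            continue
        sp_rows = []
        for var in variables:
            xv = logx[var].reindex(counts.index.get_level_values(0)).to_numpy()
            xs = (xv - xv.mean()) / xv.std(ddof=1)
            X_lin = base.assign(x=xs)
            X_quad = base.assign(x=xs, x2=xs**2)
            shape, sign, model_aicc, fit = "none", "", np.nan, None
            try:
                lin = fit_glm(y, X_lin, offsets.to_numpy(), family)
            except (RuntimeError, np.linalg.LinAlgError):
                lin = None
            try:
                quad = fit_glm(y, X_quad, offsets.to_numpy(), family)
            except (RuntimeError, np.linalg.LinAlgError):
                quad = None
            lin_ok = lin is not None and lin.aicc < null_fit.aicc
            quad_ok = quad is not None and quad.aicc < null_fit.aicc
            if quad_ok and lin is not None:
                lrt = 2 * (quad.loglik - lin.loglik)
                quad_ok = stats.chi2.sf(max(lrt, 0.0), 1) < quad_alpha
            if quad_ok:
                shape, fit = "quadratic", quad
            elif lin_ok:
                shape, fit = "linear", lin
            if fit is not None:
                sign = _classify_sign(fit, shape, xs)
                model_aicc = fit.aicc
            sp_rows.append({"species": sp, "variable": var, "family": family,
                            "shape": shape, "sign": sign,
                            "aicc": model_aicc, "null_aicc": null_fit.aicc})
        retained = [r["aicc"] for r in sp_rows if r["shape"] != "none"]
        best = min(retained) if retained else np.nan
        for r in sp_rows:
            r["delta_aicc_vs_best"] = r["aicc"] - best if r["shape"] != "none" \
                else np.nan
            r["plausible"] = bool(r["shape"] != "none"
                                  and r["aicc"] <= best + 2.0)
        rows.extend(sp_rows)
    return pd.DataFrame(rows)


def summarize_table6(summary: pd.DataFrame) -> pd.DataFrame:
    """Count species with a plausible model per descriptor.

    Per variable: how many species carry a plausible linear or quadratic
    model, split by effect sign (positive / negative; the remainder peaks at
    intermediate predictor values).
    """
    rows = []
    for var, grp in summary.groupby("variable", sort=False):
        g = grp[grp["plausible"]]
        row = {"variable": var}
        for shape in ("linear", "quadratic"):
            s = g[g["shape"] == shape]
            row[f"{shape}_total"] = len(s)
            row[f"{shape}_pos"] = int((s["sign"] == "+").sum())
            row[f"{shape}_neg"] = int((s["sign"] == "-").sum())
        row["total"] = row["linear_total"] + row["quadratic_total"]
        row["total_pos"] = row["linear_pos"] + row["quadratic_pos"]
        row["total_neg"] = row["linear_neg"] + row["quadratic_neg"]
        rows.append(row)
    return pd.DataFrame(rows).set_index("variable")
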