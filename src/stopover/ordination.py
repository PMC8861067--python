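"""Redundancy analysis of composition on island descriptors.

RDA here is the PCA of the fitted values of a multivariate linear
regression of the (column-centered) chord-transformed community matrix on
standardized predictors. Explained variance is adjusted with Ezekiel's
formula, R2_adj = 1 - (1 - R2)(N - 1)/(N - m - 1), and the two-block
variance partition into unique and shared fractions is expressed on the
adjusted scale.

Island descriptors are natural-log transformed before use; non-positive
values (a zero distance) are floored at 0.1 km first.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats

from .transforms import TransformedMatrix

LOG_FLOOR = 0.1


@dataclasses.dataclass
class RdaResult:
    eigenvalues: np.ndarray          # canonical eigenvalues, non-increasing
    prop_total: np.ndarray           # % of total response variance per axis
    prop_constrained: np.ndarray     # % of constrained variance per axis
    site_scores: pd.DataFrame        # samples x axes
    species_scores: pd.DataFrame     # species x axes
    biplot_scores: pd.DataFrame      # predictor correlations with axes
    axis_p: np.ndarray | None        # per-axis permutation p
    r2: float
    r2_adj: float
    n: int
    m: int

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


@dataclasses.dataclass
class VarPartResult:
    """Two-block variance partition on the adjusted-R2 scale."""

    geo_unique: float     # a
    shared: float         # b (not testable)
    hab_unique: float     # c
    residual: float
    r2_adj_geo: float
    r2_adj_hab: float
    r2_adj_all: float


def prepare_predictors(descriptors: pd.DataFrame, variables: list[str],
                       floor: float = LOG_FLOOR) -> pd.DataFrame:
    """Natural-log transform descriptor columns, flooring at ``floor``."""
    out = {}
    for var in variables:
        x = descriptors[var].astype(float).clip(lower=floor)
        out[var] = np.log(x)
    return pd.DataFrame(out, index=descriptors.index)


def expand_to_samples(predictors: pd.DataFrame, sample_index: pd.MultiIndex
                      ) -> pd.DataFrame:
    """Repeat island-level predictor rows once per island-year sample."""
    islands = sample_index.get_level_values(0)
    out = predictors.reindex(islands)
    out.index = sample_index
    return out


def vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor of each column regressed on the others."""
    X = X.astype(float)
    if X.shape[1] < 2:
        return pd.Series(1.0, index=X.columns)
    out = {}
    for col in X.columns:
        others = X.drop(columns=col)
        if X[col].std() == 0:
            raise ValueError(f"constant column {col!r}")
        A = np.column_stack([np.ones(len(X)), others.to_numpy()])
        y = X[col].to_numpy()
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[col] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def vif_filter(X: pd.DataFrame, threshold: float = 10.0
               ) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Iteratively drop the highest-VIF column until all VIFs < threshold."""
    if X.shape[1] < 2:
        raise ValueError("need >=2 predictors")
    if (X.std() == 0).any():
        bad = list(X.columns[X.std() == 0])
        raise ValueError(f"constant column(s): {bad}")
    X = X.copy()
    trace: list[tuple[str, float]] = []
    while X.shape[1] >= 2:
        v = vif(X)
        if (v < threshold).all():
            break
        worst = v.idxmax()
        trace.append((worst, float(v[worst])))
        X = X.drop(columns=worst)
    return X, trace


def ezekiel_adjust(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjusted R2: 1 - (1-R2)(n-1)/(n-m-1)."""
    if n - m - 1 <= 0:
        raise ValueError("adjusted R2 undefined: n must exceed m + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


def _design(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Center and scale predictor columns to unit SD."""
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant predictor column")
    return Xc / sd


def _fit(Yc: np.ndarray, Xs: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    return Xs @ coef


def _eigen(fitted: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s > s[0] * 1e-9 if s[0] > 0 else s > 0
    u, s, vt = u[:, keep], s[keep], vt[keep]
    return s**2 / (n - 1), u * s, vt.T


def rda(tm, predictors: pd.DataFrame, n_perm: int = 0, seed: int = 0) -> RdaResult:
    """Constrained ordination of the community matrix on predictors.

    ``tm`` may be a TransformedMatrix or any samples x species DataFrame;
    predictor rows must align with samples. Axis permutation p-values (when
    ``n_perm > 0``) compare each observed canonical eigenvalue with its rank
    counterpart under row permutations of the response.
    """
    Y = tm.values if isinstance(tm, TransformedMatrix) else tm
    if len(Y) != len(predictors):
        raise ValueError("response and predictor rows must align")
    Xs = _design(predictors)
    rank = np.linalg.matrix_rank(Xs)
    if rank < Xs.shape[1]:
        raise ValueError(
            f"rank-deficient predictors: rank {rank} < {Xs.shape[1]} columns "
            f"({list(predictors.columns)}); remove aliased variables"
        )
    Yc = Y.to_numpy(dtype=float) - Y.to_numpy(dtype=float).mean(axis=0)
    n, m = Yc.shape[0], Xs.shape[1]
    fitted = _fit(Yc, Xs)
    ss_total = float((Yc**2).sum())
    ss_fit = float((fitted**2).sum())
    r2 = ss_fit / ss_total if ss_total > 0 else 0.0
    eig, site, species = _eigen(fitted, n)

    # orient each axis so the largest-|score| species loads positively
    for a in range(site.shape[1]):
        j = np.argmax(np.abs(species[:, a]))
        if species[j, a] < 0:
            species[:, a] *= -1
            site[:, a] *= -1

    total_var = ss_total / (n - 1)
    axes = [f"RDA{a + 1}" for a in range(len(eig))]
    site_df = pd.DataFrame(site, index=Y.index, columns=axes)
    species_df = pd.DataFrame(species, index=Y.columns, columns=axes)
    biplot = pd.DataFrame(
        [[np.corrcoef(predictors[c], site[:, a])[0, 1] for a in range(len(eig))]
         for c in predictors.columns],
        index=predictors.columns, columns=axes)

    axis_p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(eig))
        for _ in range(n_perm):
            perm = rng.permutation(n)
            f_perm = _fit(Yc[perm], Xs)
            eig_perm, _, _ = _eigen(f_perm, n)
            k = min(len(eig_perm), len(eig))
            exceed[:k] += eig_perm[:k] >= eig[:k]
        axis_p = (1 + exceed) / (n_perm + 1)

    return RdaResult(
        eigenvalues=eig,
        prop_total=100 * eig / total_var,
        prop_constrained=100 * eig / eig.sum() if eig.sum() > 0 else eig,
        site_scores=site_df, species_scores=species_df, biplot_scores=biplot,
        axis_p=axis_p, r2=r2, r2_adj=ezekiel_adjust(r2, n, m), n=n, m=m,
    )


def _r2(Yc: np.ndarray, X: np.ndarray | None) -> float:
    if X is None or X.shape[1] == 0:
        return 0.0
    fitted = _fit(Yc, _design(X))
    return float((fitted**2).sum() / (Yc**2).sum())


def forward_select(tm, predictors: pd.DataFrame, alpha: float = 0.05,
                   n_perm: int = 199, seed: int = 0,
                   adjr2_stop: bool = False) -> list[str]:
    """Greedy forward selection of predictors by permutation p-value.

    At each step the candidate with the largest partial pseudo-F is tested
    by permuting the residuals of the current model; it enters if p < alpha.
    The optional ``adjr2_stop`` additionally halts once a trial set's
    adjusted R2 would exceed that of the full predictor set — a stricter
    scope rule that guards against greedy inflation at the cost of
    sometimes rejecting a genuinely dominant predictor, hence off by
    default. Deterministic under a fixed seed.
    """
    Y = tm.values if isinstance(tm, TransformedMatrix) else tm
    Yc = Y.to_numpy(dtype=float) - Y.to_numpy(dtype=float).mean(axis=0)
    n = len(Yc)
    candidates = list(predictors.columns)
    if not candidates:
        return []
    r2_full = _r2(Yc, predictors.to_numpy())
    r2_adj_full = ezekiel_adjust(r2_full, n, len(candidates))
    selected: list[str] = []
    rng = np.random.default_rng(seed)

    def partial_f(Yw, cols_base, col_new):
        X0 = predictors[cols_base].to_numpy() if cols_base else None
        X1 = predictors[cols_base + [col_new]].to_numpy()
        ss_tot = (Yw**2).sum()
        r2_0 = _r2(Yw, X0)
        r2_1 = _r2(Yw, X1)
        m1 = len(cols_base) + 1
        denom = (1 - r2_1) * ss_tot / (n - m1 - 1)
        return ((r2_1 - r2_0) * ss_tot) / denom if denom > 0 else np.inf

    while candidates:
        fs = {c: partial_f(Yc, selected, c) for c in candidates}
        best = max(fs, key=fs.get)
        f_obs = fs[best]
        # residual permutation under the current (reduced) model
        X0 = predictors[selected].to_numpy() if selected else None
        fitted0 = _fit(Yc, _design(X0)) if X0 is not None else np.zeros_like(Yc)
        resid0 = Yc - fitted0
        count = 0
        for _ in range(n_perm):
            Yp = fitted0 + resid0[rng.permutation(n)]
            Yp = Yp - Yp.mean(axis=0)
            if partial_f(Yp, selected, best) >= f_obs:
                count += 1
        p = (1 + count) / (n_perm + 1)
        if p >= alpha:
            break
        trial = selected + [best]
        if adjr2_stop:
            r2_trial = _r2(Yc, predictors[trial].to_numpy())
            if ezekiel_adjust(r2_trial, n, len(trial)) > r2_adj_full:
                break
        selected = trial
        candidates.remove(best)
    return selected


def varpart2(tm, x_geo: pd.DataFrame, x_hab: pd.DataFrame) -> VarPartResult:
    """Partition adjusted explained variance between two predictor blocks.

    a = unique to the first block, c = unique to the second,
    b = shared (not testable), residual = 1 - R2_adj(both blocks).
    """
    Y = tm.values if isinstance(tm, TransformedMatrix) else tm
    Yc = Y.to_numpy(dtype=float) - Y.to_numpy(dtype=float).mean(axis=0)
    n = len(Yc)
    both = pd.concat([x_geo, x_hab], axis=1)

    def adj(X):
        # rank, not column count: overlapping blocks make the union collinear
        Xs = _design(X.to_numpy())
        return ezekiel_adjust(_r2(Yc, X.to_numpy()), n,
                              int(np.linalg.matrix_rank(Xs)))

    r2_geo, r2_hab, r2_all = adj(x_geo), adj(x_hab), adj(both)
    a = r2_all - r2_hab
    c = r2_all - r2_geo
    b = r2_geo + r2_hab - r2_all
    return VarPartResult(geo_unique=a, shared=b, hab_unique=c,
                         residual=1.0 - r2_all,
                         r2_adj_geo=r2_geo, r2_adj_hab=r2_hab, r2_adj_all=r2_all)


def partial_rda_test(tm, X: pd.DataFrame, Z: pd.DataFrame,
                     n_perm: int = 199, seed: int = 0) -> PermTestResultLike:
    """Permutation test of X's unique contribution, conditioning on Z.

    Both the response and X are residualized on Z; the partial pseudo-F is
    tested by permuting the response residuals.
    """
    Y = tm.values if isinstance(tm, TransformedMatrix) else tm
    Yc = Y.to_numpy(dtype=float) - Y.to_numpy(dtype=float).mean(axis=0)
    n = len(Yc)
    Zs = _design(Z)
    Yr = Yc - _fit(Yc, Zs)
    Xr = _design(X) - _fit(_design(X), Zs)
    m_x, m_z = X.shape[1], Z.shape[1]

    def pseudo_f(Yw):
        fitted = _fit(Yw, Xr)
        ss_fit = (fitted**2).sum()
        ss_res = ((Yw - fitted) ** 2).sum()
        return (ss_fit / m_x) / (ss_res / (n - m_x - m_z - 1))

    f_obs = pseudo_f(Yr)
    rng = np.random.default_rng(seed)
    count = sum(pseudo_f(Yr[rng.permutation(n)]) >= f_obs for _ in range(n_perm))
    p = (1 + count) / (n_perm + 1)
    return {"F": float(f_obs), "df": (m_x, n - m_x - m_z - 1), "p": p,
            "n_permutations": n_perm}


PermTestResultLike = dict


def axis_variable_association(result: RdaResult, predictors: pd.DataFrame,
                              n_axes: int = 3) -> pd.DataFrame:
    """Predictor-axis correlations with island-level significance.

    The Pearson r is computed across all island-year samples; the p-value
    comes from regressing island-mean axis scores on the island's predictor
    value (one point per island), which respects the island as the
    exchangeability unit for island-constant descriptors.
    """
    n_axes = min(n_axes, result.n_axes)
    scores = result.site_scores.iloc[:, :n_axes]
    island_scores = scores.groupby(level=0, sort=False).mean()
    island_pred = predictors.groupby(predictors.index.get_level_values(0),
                                     sort=False).mean()
    island_pred = island_pred.reindex(island_scores.index)
    rows = []
    for var in predictors.columns:
        for axis in scores.columns:
            r = float(np.corrcoef(predictors[var], scores[axis])[0, 1])
            slope_r, p = stats.pearsonr(island_pred[var], island_scores[axis])
            rows.append({"variable": var, "axis": axis, "r": r,
                         "p_island": float(p)})
    return pd.DataFrame(rows)


def species_axis_correlations(result: RdaResult, tm, n_axes: int = 3,
                              bonferroni: bool = True) -> pd.DataFrame:
    """Correlation of each species' transformed abundance with axis scores.

    Raw two-sided p-values use the t approximation; with ``bonferroni`` the
    raw p is multiplied by the number of tests (species x axes), capped at 1.
    """
    Y = tm.values if isinstance(tm, TransformedMatrix) else tm
    n_axes = min(n_axes, result.n_axes)
    scores = result.site_scores.iloc[:, :n_axes]
    m_tests = Y.shape[1] * n_axes
    rows = []
    for sp in Y.columns:
        row = {"species": sp}
        for axis in scores.columns:
            y = Y[sp].to_numpy()
            if y.std() == 0:
                r, p = np.nan, np.nan
            else:
                r, p = stats.pearsonr(y, scores[axis].to_numpy())
            row[f"{axis}_r"] = float(r)
            row[f"{axis}_p"] = float(p)
            if bonferroni:
                row[f"{axis}_p_bonf"] = min(1.0, float(p) * m_tests) \
                    if np.isfinite(p) else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("species")
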