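"""Wing-shape comparisons between species response groups, with
phylogenetic generalized least squares.

The Kipp index (100 x primary projection / wing length) measures wing
pointedness. Group differences are tested with GLS whose residual
covariance is sigma^2 V(lambda): V holds shared root-to-tip path lengths
under Brownian motion and Pagel's lambda scales its off-diagonals. lambda
is estimated by profile maximum likelihood, by default over the
conventional interval [0, 1]; the search can optionally be extended down
to the smallest lambda keeping V(lambda) positive definite, which is
negative and makes negative estimates (as unbounded GLS machinery
produces on real comparative data) reachable. A likelihood-ratio test
against lambda = 0 decides whether the phylogenetic model is kept; with
the [0, 1] restriction this test is conservative under no signal (the
null distribution is a boundary mixture).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats


def kipp_index(primary_projection, wing_length):
    """Kipp index in percent: 100 * primary projection / wing length."""
    pp = np.asarray(primary_projection, dtype=float)
    wl = np.asarray(wing_length, dtype=float)
    if (pp <= 0).any() or (wl <= 0).any():
        raise ValueError("primary projection and wing length must be > 0")
    if (pp >= wl).any():
        raise ValueError("primary projection must be smaller than wing length")
    out = 100.0 * pp / wl
    return float(out) if out.ndim == 0 else out


def kipp_summary(individuals: pd.DataFrame) -> pd.DataFrame:
    """Per-species mean and SD of the Kipp index over measured individuals.

    ``individuals`` columns: species, primary_projection, wing_length.
    """
    vals = kipp_index(individuals["primary_projection"],
                      individuals["wing_length"])
    df = pd.DataFrame({"species": individuals["species"], "kipp": vals})
    out = df.groupby("species")["kipp"].agg(kipp_mean="mean", kipp_sd="std")
    return out


@dataclasses.dataclass
class PhyloCovariance:
    taxa: list[str]
    matrix: np.ndarray  # V[a,b] = depth of MRCA(a,b); diagonal = tip depths


@dataclasses.dataclass
class PglsFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    df_resid: int
    sigma2: float
    lam: float
    loglik: float
    loglik_lambda0: float
    lrt_stat: float
    lrt_p: float
    n: int


def phylo_cov(tree) -> PhyloCovariance:
    """Brownian-motion covariance: shared root-to-tip path length per pair."""
    tree.calc_node_root_distances()
    leaves = tree.leaf_nodes()
    taxa = [lf.taxon.label for lf in leaves]
    depth = {lf.taxon.label: lf.root_distance for lf in leaves}
    n = len(taxa)
    V = np.zeros((n, n))
    pdm = tree.phylogenetic_distance_matrix()
    taxon_of = {lf.taxon.label: lf.taxon for lf in leaves}
    for i, a in enumerate(taxa):
        V[i, i] = depth[a]
        for j in range(i + 1, n):
            b = taxa[j]
            d = pdm.patristic_distance(taxon_of[a], taxon_of[b])
            V[i, j] = V[j, i] = 0.5 * (depth[a] + depth[b] - d)
    return PhyloCovariance(taxa, V)


def lambda_transform(V: np.ndarray, lam: float) -> np.ndarray:
    """Scale off-diagonal covariances by lambda, keeping tip variances."""
    out = lam * V
    np.fill_diagonal(out, np.diag(V))
    return out


def _is_pd(M: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(M)
        return True
    except np.linalg.LinAlgError:
        return False


def lambda_min(V: np.ndarray, lower: float = -3.0, tol: float = 1e-4) -> float:
    """Smallest lambda keeping V(lambda) positive definite (bisection)."""
    lo, hi = lower, 0.0
    if _is_pd(lambda_transform(V, lo)):
        return lo
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _is_pd(lambda_transform(V, mid)):
            hi = mid
        else:
            lo = mid
    return hi


def _gls(y: np.ndarray, X: np.ndarray, W: np.ndarray):
    """GLS fit pieces at a fixed covariance W (up to sigma^2)."""
    c, low = linalg.cho_factor(W, lower=True)
    Wi_X = linalg.cho_solve((c, low), X)
    Wi_y = linalg.cho_solve((c, low), y)
    XtWiX = X.T @ Wi_X
    beta = np.linalg.solve(XtWiX, X.T @ Wi_y)
    resid = y - X @ beta
    Wi_r = linalg.cho_solve((c, low), resid)
    rss = float(resid @ Wi_r)
    logdet = 2.0 * float(np.sum(np.log(np.diag(c))))
    return beta, XtWiX, rss, logdet


def _loglik(y, X, W) -> float:
    n = len(y)
    _, _, rss, logdet = _gls(y, X, W)
    sigma2 = rss / n
    if sigma2 <= 0:
        return -np.inf
    return -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet + n)


def fit_pgls(y, X, V: np.ndarray, lam: float | str = "ml",
             grid_size: int = 41,
             lower: float | str = 0.0) -> PglsFit:
    """PGLS of a trait on a design matrix with covariance sigma^2 V(lambda).

    ``lam='ml'`` profiles lambda over a grid on [``lower``, 1] followed by
    local refinement; a float fixes it. ``lower='pd'`` extends the search
    down to the smallest lambda keeping V(lambda) positive definite —
    negative estimates (as unbounded GLS machinery can produce) become
    reachable, but near that boundary the profile likelihood can spike
    against the singularity, so the default keeps the conventional [0, 1]
    interval. Coefficient t-tests use residual df = n - p.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else \
        [f"x{i}" for i in range(np.asarray(X).shape[1])]
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError("PGLS needs n > p + 1")
    if V.shape != (n, n):
        raise ValueError("V must be n x n aligned with the trait vector")

    def nll(l):
        W = lambda_transform(V, l)
        if not _is_pd(W):
            return np.inf
        return -_loglik(y, X, W)

    if lam == "ml":
        lmin = lambda_min(V) + 1e-3 if lower == "pd" else float(lower)
        grid = np.unique(np.concatenate([np.linspace(lmin, 1.0, grid_size),
                                         [0.0, 1.0]]))
        grid = grid[grid >= lmin]
        vals = np.array([nll(l) for l in grid])
        i = int(np.argmin(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        if hi > lo:
            res = optimize.minimize_scalar(nll, bounds=(lo, hi),
                                           method="bounded")
            lam_hat = float(res.x) if res.fun <= vals[i] else float(grid[i])
        else:
            lam_hat = float(grid[i])
    else:
        lam_hat = float(lam)
        if not _is_pd(lambda_transform(V, lam_hat)):
            raise ValueError(f"V(lambda) not positive definite at {lam_hat}")

    W = lambda_transform(V, lam_hat)
    beta, XtWiX, rss, _ = _gls(y, X, W)
    sigma2_ml = rss / n
    sigma2_hat = rss / (n - p)
    cov = sigma2_hat * np.linalg.inv(XtWiX)
    bse = np.sqrt(np.diag(cov))
    tvals = beta / bse
    df = n - p
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    ll = _loglik(y, X, W)
    ll0 = _loglik(y, X, lambda_transform(V, 0.0))
    lrt = 2.0 * (ll - ll0)
    return PglsFit(
        params=pd.Series(beta, index=names), bse=pd.Series(bse, index=names),
        tvalues=pd.Series(tvals, index=names),
        pvalues=pd.Series(pvals, index=names),
        df_resid=df, sigma2=float(sigma2_ml), lam=lam_hat,
        loglik=float(ll), loglik_lambda0=float(ll0),
        lrt_stat=float(max(lrt, 0.0)),
        lrt_p=float(stats.chi2.sf(max(lrt, 0.0), 1)), n=n,
    )


def group_tests(traits: pd.DataFrame, groups: pd.DataFrame, tree,
                interaction_alpha: float = 0.05,
                lrt_alpha: float = 0.05,
                lower: float | str = 0.0) -> pd.DataFrame:
    """PGLS comparisons of each wing trait between response groups.

    ``groups`` holds one or two binary indicator columns (e.g. responds to
    island area, responds to distance-to-southern-land). With two
    indicators the interaction is fitted first and dropped if not
    significant. If the lambda-ML model does not beat lambda = 0 by LRT,
    the simpler lambda = 0 fit is reported.
    """
    cov = phylo_cov(tree)
    rows = []
    for trait in traits.columns:
        y_all = traits[trait].dropna()
        taxa = [t for t in cov.taxa if t in y_all.index and t in groups.index]
        if len(taxa) < len(groups.columns) + 3:
            raise ValueError(f"too few species with {trait} data")
        idx = [cov.taxa.index(t) for t in taxa]
        V = cov.matrix[np.ix_(idx, idx)]
        y = y_all.reindex(taxa).to_numpy()
        G = groups.reindex(taxa).astype(float)
        for col in G.columns:
            m = int(G[col].sum())
            if m < 2 or len(taxa) - m < 2:
                raise ValueError(f"group too small for indicator {col!r}")
        X = pd.DataFrame({"intercept": 1.0}, index=taxa)
        for col in G.columns:
            X[col] = G[col]
        used_interaction = False
        if G.shape[1] == 2:
            c1, c2 = G.columns
            Xi = X.assign(interaction=G[c1] * G[c2])
            if Xi["interaction"].std() > 0:
                fit_i = fit_pgls(y, Xi, V, lower=lower)
                if fit_i.pvalues["interaction"] < interaction_alpha:
                    X, used_interaction = Xi, True
        fit_ml = fit_pgls(y, X, V, lower=lower)
        lrt_p = fit_ml.lrt_p
        fit = fit_ml if lrt_p < lrt_alpha else fit_pgls(y, X, V, lam=0.0)
        for col in [c for c in X.columns if c != "intercept"]:
            rows.append({
                "trait": trait, "term": col, "n": fit.n,
                "coef": fit.params[col], "t": fit.tvalues[col],
                "df": fit.df_resid, "p": fit.pvalues[col],
                "lambda": fit.lam, "lrt_p": lrt_p,
                "interaction_kept": used_interaction,
            })
    return pd.DataFrame(rows)
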