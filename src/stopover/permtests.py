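"""Permutation inference on composition in chord space.

Chord-transformed data live in a Euclidean space, so the PERMANOVA
pseudo-F can be computed directly from sums of squares of the transformed
matrix; it is identical to the pseudo-F defined on the matrix of pairwise
chord distances. The permutation scheme is unrestricted row-label
permutation, with the observed statistic included in the reference set, so
p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np
import pandas as pd

from .transforms import TransformedMatrix


@dataclasses.dataclass
class PermTestResult:
    statistic: float
    df: tuple[int, int]
    p_value: float
    n_permutations: int
    seed: int
    method: str


def _as_matrix_groups(tm, grouping):
    if isinstance(tm, TransformedMatrix):
        X = tm.values.to_numpy(dtype=float)
        if grouping is None:
            groups = tm.values.index.get_level_values(0).to_numpy()
        else:
            groups = np.asarray(grouping)
    else:
        X = np.asarray(tm, dtype=float)
        groups = np.asarray(grouping)
    if len(groups) != len(X):
        raise ValueError("grouping length must match number of rows")
    return X, groups


def _group_layout(groups):
    labels, codes = np.unique(groups, return_inverse=True)
    sizes = np.bincount(codes)
    if len(labels) < 2:
        raise ValueError("need >=2 groups")
    if (sizes < 2).any():
        small = labels[sizes < 2]
        raise ValueError(f"every group needs >=2 samples; too small: {list(small)}")
    order = np.argsort(codes, kind="stable")
    offsets = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    return labels, codes, sizes, order, offsets


def _pseudo_f_stats(X, sizes, offsets, perm_rows):
    """Pseudo-F for row orderings where groups are contiguous blocks."""
    n = len(X)
    g = len(sizes)
    grand = X.sum(axis=0)
    ss_total = float((X**2).sum() - (grand**2).sum() / n)
    Xp = X[perm_rows]
    gs = np.add.reduceat(Xp, offsets, axis=0)
    ss_between = float((gs**2 / sizes[:, None]).sum() - (grand**2).sum() / n)
    ss_within = ss_total - ss_between
    df_b, df_w = g - 1, n - g
    if ss_within <= 1e-300:
        return np.inf, ss_total
    return (ss_between / df_b) / (ss_within / df_w), ss_total


def permanova(tm, grouping=None, n_perm: int = 999, seed: int = 0) -> PermTestResult:
    """One-way PERMANOVA of composition against a grouping factor.

    F = (SS_between/df_b)/(SS_within/df_w) on the (chord-transformed)
    response rows; the null distribution comes from permuting row labels.
    """
    X, groups = _as_matrix_groups(tm, grouping)
    _, codes, sizes, order, offsets = _group_layout(groups)
    f_obs, _ = _pseudo_f_stats(X, sizes, offsets, order)
    rng = np.random.default_rng(seed)
    n = len(X)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)[order]
        f_perm, _ = _pseudo_f_stats(X, sizes, offsets, perm)
        if f_perm >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermTestResult(float(f_obs), (len(sizes) - 1, n - len(sizes)), p,
                          n_perm, seed, "permanova")


def _centroid_distances(X, codes, sizes, bias_adjust):
    g = len(sizes)
    cent = np.zeros((g, X.shape[1]))
    np.add.at(cent, codes, X)
    cent /= sizes[:, None]
    d = np.linalg.norm(X - cent[codes], axis=1)
    if bias_adjust:
        d = d * np.sqrt(sizes[codes] / (sizes[codes] - 1.0))
    return d


def _anova_f(d, codes, sizes):
    n = len(d)
    g = len(sizes)
    grand = d.sum()
    gs = np.bincount(codes, weights=d, minlength=g)
    ss_total = (d**2).sum() - grand**2 / n
    ss_between = (gs**2 / sizes).sum() - grand**2 / n
    ss_within = ss_total - ss_between
    if ss_within <= 0:
        return np.inf
    return (ss_between / (g - 1)) / (ss_within / (n - g))


def dispersion_test(tm, grouping=None, bias_adjust: bool = True,
                    n_perm: int = 999, seed: int = 0) -> PermTestResult:
    """Homogeneity of multivariate dispersion between groups.

    Each sample's Euclidean distance to its group centroid in chord space is
    the dispersion datum; with ``bias_adjust`` each group's distances are
    scaled by sqrt(m/(m-1)) to correct small-sample bias. The F statistic
    is the one-way ANOVA F on those distances; the permutation null
    reassigns raw rows to groups and recomputes centroids and distances.
    """
    X, groups = _as_matrix_groups(tm, grouping)
    _, codes, sizes, _, _ = _group_layout(groups)
    d_obs = _centroid_distances(X, codes, sizes, bias_adjust)
    f_obs = _anova_f(d_obs, codes, sizes)
    rng = np.random.default_rng(seed)
    n = len(X)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        d_perm = _centroid_distances(X[perm], codes, sizes, bias_adjust)
        if _anova_f(d_perm, codes, sizes) >= f_obs:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermTestResult(float(f_obs), (len(sizes) - 1, n - len(sizes)), p,
                          n_perm, seed, "dispersion")


def group_dispersions(tm, grouping=None, bias_adjust: bool = True) -> pd.Series:
    """Mean (bias-adjusted) distance to group centroid, per group."""
    X, groups = _as_matrix_groups(tm, grouping)
    labels, codes, sizes, _, _ = _group_layout(groups)
    d = _centroid_distances(X, codes, sizes, bias_adjust)
    means = np.bincount(codes, weights=d) / sizes
    return pd.Series(means, index=labels, name="dispersion")


def pairwise_permanova(tm, grouping=None, n_perm: int = 999, seed: int = 0,
                       method: str = "fdr_bh") -> pd.DataFrame:
    """All pairwise PERMANOVAs with FDR (Benjamini-Hochberg) adjustment.

    Returns a long table (group1, group2, F, p_raw, p_adj); adjustment is
    across the n(n-1)/2 raw p-values.
    """
    from statsmodels.stats.multitest import multipletests

    X, groups = _as_matrix_groups(tm, grouping)
    labels = np.unique(groups)
    rows = []
    rng = np.random.default_rng(seed)
    for a, b in itertools.combinations(labels, 2):
        mask = (groups == a) | (groups == b)
        sub_seed = int(rng.integers(2**31 - 1))
        res = permanova(X[mask], groups[mask], n_perm=n_perm, seed=sub_seed)
        rows.append({"group1": a, "group2": b,
                     "F": res.statistic, "p_raw": res.p_value})
    out = pd.DataFrame(rows)
    if len(out) > 1:
        out["p_adj"] = multipletests(out["p_raw"].values, method=method)[1]
    else:
        out["p_adj"] = out["p_raw"]
    return out
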