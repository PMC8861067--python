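"""Eligibility filters and the chord transformation.

The sample unit throughout is the island-year: one row of counts per
species per island per eligible year. The chord transformation scales each
row to unit Euclidean norm, so that Euclidean distances between transformed
rows equal chord distances between the raw abundance profiles; distances are
then bounded by sqrt(2), attained when two samples share no species.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("stopover")


@dataclasses.dataclass
class CommunityMatrix:
    """Island-year x species count matrix.

    ``counts`` has a (island, year) MultiIndex and one column per species.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.nlevels != 2:
            raise ValueError("counts must be indexed by (island, year)")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate (island, year) rows")

    @property
    def islands(self) -> list:
        return list(self.counts.index.get_level_values(0).unique())

    @property
    def species(self) -> list:
        return list(self.counts.columns)

    def years_per_island(self) -> pd.Series:
        """Number of sampled years per island (Y_i)."""
        return self.counts.groupby(level=0, sort=False).size()


@dataclasses.dataclass
class TransformedMatrix:
    """Chord-transformed community matrix with the group means used downstream.

    ``values``        unit-norm rows y_ijk (island-year x species)
    ``island_means``  per-island mean of transformed values over years (ybar_ij)
    ``species_means`` grand mean per species over all rows (ybar_j)
    """

    values: pd.DataFrame
    island_means: pd.DataFrame
    species_means: pd.Series

    @property
    def islands(self) -> list:
        return list(self.values.index.get_level_values(0).unique())

    def years_per_island(self) -> pd.Series:
        return self.values.groupby(level=0, sort=False).size()


def filter_species(
    records: pd.DataFrame, min_years: int = 5, min_islands: int = 5
) -> tuple[pd.DataFrame, list[str]]:
    """Drop species captured too rarely to carry compositional signal.

    A species is retained if it was ringed (count > 0) in at least
    ``min_years`` distinct years OR on at least ``min_islands`` distinct
    islands — the disjunction, so a species concentrated in one good year
    across many islands still qualifies.

    Returns the retained records and the list of dropped species.
    """
    present = records[records["count"] > 0]
    n_years = present.groupby("species")["year"].nunique()
    n_islands = present.groupby("species")["island"].nunique()
    stats = pd.DataFrame({"n_years": n_years, "n_islands": n_islands}).fillna(0)
    keep = stats[(stats.n_years >= min_years) | (stats.n_islands >= min_islands)].index
    all_species = records["species"].unique()
    dropped = sorted(set(all_species) - set(keep))
    if dropped:
        logger.info("filter_species: dropped %d of %d species: %s",
                    len(dropped), len(all_species), dropped)
    if len(keep) == 0:
        logger.warning("filter_species: no species retained")
    return records[records["species"].isin(keep)].copy(), dropped


def _fortnights(season_start: str = "04-16", season_end: str = "05-15"):
    sm, sd = map(int, season_start.split("-"))
    em, ed = map(int, season_end.split("-"))
    return (sm, sd), (em, ed)


def filter_years(
    effort: pd.DataFrame,
    season_start: str = "04-16",
    season_end: str = "05-15",
    min_days_per_fortnight: int = 7,
) -> list[tuple[str, int]]:
    """Island-years with enough ringing effort in both halves of the season.

    An (island, year) is eligible iff nets were open on at least
    ``min_days_per_fortnight`` distinct days in the first fortnight
    (season start to month end) AND in the second (month start to season
    end). Effort dates outside the window are ignored (logged).
    """
    (sm, sd), (em, ed) = _fortnights(season_start, season_end)
    eff = effort.copy().reset_index(drop=True)
    eff["year"] = eff["date"].dt.year
    eff["in_first"] = (eff["date"].dt.month == sm) & (eff["date"].dt.day >= sd)
    eff["in_second"] = (eff["date"].dt.month == em) & (eff["date"].dt.day <= ed)
    outside = ~(eff["in_first"] | eff["in_second"])
    if outside.any():
        logger.info("filter_years: ignoring %d effort days outside %s..%s window",
                    int(outside.sum()), season_start, season_end)
    eligible = []
    for (island, year), grp in eff[~outside].groupby(["island", "year"]):
        d1 = grp.loc[grp["in_first"], "date"].nunique()
        d2 = grp.loc[grp["in_second"], "date"].nunique()
        if d1 >= min_days_per_fortnight and d2 >= min_days_per_fortnight:
            eligible.append((island, int(year)))
    return sorted(eligible)


def pivot(records: pd.DataFrame) -> CommunityMatrix:
    """Pivot long capture records into an island-year x species matrix.

    Absent (island, year, species) combinations become 0. Island-years whose
    row total is zero are removed (the chord transform is undefined there).
    """
    wide = (
        records.pivot_table(index=["island", "year"], columns="species",
                            values="count", aggfunc="sum", fill_value=0)
        .sort_index()
    )
    wide.columns.name = None
    totals = wide.sum(axis=1)
    if (totals == 0).any():
        zero_rows = list(wide.index[totals == 0])
        logger.warning("pivot: dropping %d all-zero island-year rows: %s",
                       len(zero_rows), zero_rows)
        wide = wide[totals > 0]
    return CommunityMatrix(wide)


def chord_transform(matrix: CommunityMatrix) -> TransformedMatrix:
    """Scale each island-year row to unit Euclidean norm.

    y'_rj = y_rj / sqrt(sum_j y_rj^2). Also computes the per-island means of
    the transformed values over years (ybar_ij) and the grand species means
    (ybar_j), the quantities the beta-diversity partition is built from.
    """
    counts = matrix.counts.astype(float)
    norms = np.sqrt((counts**2).sum(axis=1))
    if (norms == 0).any():
        bad = counts.index[norms == 0][0]
        raise ValueError(f"chord_transform: zero row for sample {bad}")
    values = counts.div(norms, axis=0)
    island_means = values.groupby(level=0, sort=False).mean()
    species_means = values.mean(axis=0)
    return TransformedMatrix(values, island_means, species_means)
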