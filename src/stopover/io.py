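"""Reading, validation and writing of every table the pipeline touches.

All tables are CSV with a header row, UTF-8, "." decimal separator; trees
are single-tree Newick files. Species and island identifiers are opaque
strings (ringing-scheme acronyms in practice).
"""

from __future__ import annotations

import dataclasses
import logging
from importlib import resources
from pathlib import Path

import dendropy
import pandas as pd
import yaml

logger = logging.getLogger("stopover")

CAPTURE_COLUMNS = ["island", "year", "species", "count"]
EFFORT_COLUMNS = ["island", "date", "net_length"]

#: geographic-location descriptors used as one explanatory block in ordination
GEOGRAPHIC_VARS = [
    "latitude",
    "long_km",
    "min_dist_africa",
    "str_dist_africa",
    "min_dist_land",
    "min_d_south_land",
]
#: habitat descriptors: the other explanatory block
HABITAT_VARS = ["area", "max_alt", "ndvi"]


class ParseError(ValueError):
    """Raised when an input table violates its contract."""


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ParseError(f"{what}: missing column(s) {missing}; found {list(df.columns)}")


def validate_capture_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate long-format capture records (island, year, species, count)."""
    _require_columns(df, CAPTURE_COLUMNS, "capture records")
    if len(df) == 0:
        raise ParseError("capture records: at least one record required")
    df = df.copy()
    df["island"] = df["island"].astype(str)
    df["species"] = df["species"].astype(str)
    df["year"] = pd.to_numeric(df["year"], errors="raise").astype(int)
    df["count"] = pd.to_numeric(df["count"], errors="raise")
    if (df["count"] < 0).any():
        bad = df.loc[df["count"] < 0].iloc[0]
        raise ParseError(
            f"capture records: negative count for ({bad.island},{bad.year},{bad.species})"
        )
    df["count"] = df["count"].astype(int)
    dup = df.duplicated(subset=["island", "year", "species"])
    if dup.any():
        bad = df.loc[dup].iloc[0]
        raise ParseError(
            f"capture records: duplicate key ({bad.island},{bad.year},{bad.species})"
        )
    return df[CAPTURE_COLUMNS]


def read_capture_records(path: str | Path) -> pd.DataFrame:
    return validate_capture_records(pd.read_csv(path))


def validate_effort_records(df: pd.DataFrame) -> pd.DataFrame:
    """Validate daily ringing-effort records (island, date, net_length in m)."""
    _require_columns(df, EFFORT_COLUMNS, "effort records")
    df = df.copy()
    df["island"] = df["island"].astype(str)
    df["date"] = pd.to_datetime(df["date"], errors="raise")
    df["net_length"] = pd.to_numeric(df["net_length"], errors="raise")
    if (df["net_length"] <= 0).any():
        raise ParseError("effort records: net_length must be > 0")
    return df[EFFORT_COLUMNS]


def read_effort_records(path: str | Path) -> pd.DataFrame:
    return validate_effort_records(pd.read_csv(path))


def validate_island_descriptors(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, ["island"] + GEOGRAPHIC_VARS + HABITAT_VARS, "island descriptors")
    df = df.copy()
    df["island"] = df["island"].astype(str)
    if df["island"].duplicated().any():
        raise ParseError("island descriptors: island identifiers must be unique")
    nonneg = ["long_km", "min_dist_africa", "str_dist_africa", "min_dist_land",
              "min_d_south_land", "area", "max_alt"]
    for col in nonneg:
        if (df[col] < 0).any():
            raise ParseError(f"island descriptors: {col} must be >= 0")
    if ((df["ndvi"] < -1) | (df["ndvi"] > 1)).any():
        raise ParseError("island descriptors: NDVI must lie in [-1, 1]")
    return df.set_index("island")


def read_island_descriptors(path: str | Path) -> pd.DataFrame:
    return validate_island_descriptors(pd.read_csv(path))


def load_island_table() -> pd.DataFrame:
    """Packaged table of the nine study islands.

    Columns: geographic and habitat descriptors plus the published per-island
    summaries — mean local contribution to beta diversity (``lcbd``),
    island temporal beta diversity (``bd_ti``) and the number of eligible
    study years (``years_used``).
    """
    with resources.files("stopover.data").joinpath("island_descriptors.csv").open() as fh:
        return validate_island_descriptors(pd.read_csv(fh))


def validate_trait_table(df: pd.DataFrame) -> pd.DataFrame:
    """Species wing traits: Kipp index mean/SD (%), wing aspect ratio."""
    _require_columns(df, ["species", "kipp_mean"], "trait table")
    df = df.copy()
    df["species"] = df["species"].astype(str)
    if df["species"].duplicated().any():
        raise ParseError("trait table: duplicate species")
    if ((df["kipp_mean"] <= 0) | (df["kipp_mean"] >= 100)).any():
        raise ParseError("trait table: kipp_mean must lie in (0, 100)")
    return df.set_index("species")


def read_trait_table(path: str | Path) -> pd.DataFrame:
    return validate_trait_table(pd.read_csv(path))


def read_continental_abundance(path: str | Path) -> pd.Series:
    """Continental abundance per species, in breeding pairs.

    Accepts either an ``abundance`` column or ``pairs_min``/``pairs_max``
    columns, in which case the mean of the two estimates is used.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["species"], "continental abundance")
    df["species"] = df["species"].astype(str)
    if "abundance" in df.columns:
        ab = pd.to_numeric(df["abundance"])
    elif {"pairs_min", "pairs_max"} <= set(df.columns):
        ab = (pd.to_numeric(df["pairs_min"]) + pd.to_numeric(df["pairs_max"])) / 2.0
    else:
        raise ParseError("continental abundance: need 'abundance' or 'pairs_min'/'pairs_max'")
    if (ab <= 0).any():
        raise ParseError("continental abundance: abundances must be > 0")
    return pd.Series(ab.values, index=df["species"].values, name="abundance")


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single rooted tree with branch lengths from a Newick file."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises several parse-error types
        raise ParseError(f"newick parse error in {path}: {exc}") from exc
    return validate_tree(tree)


def parse_newick(newick: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(data=newick, schema="newick")
    except Exception as exc:
        raise ParseError(f"newick parse error: {exc}") from exc
    return validate_tree(tree)


def validate_tree(tree: dendropy.Tree) -> dendropy.Tree:
    leaves = tree.leaf_nodes()
    if len(leaves) < 2:
        raise ParseError("tree must have at least 2 tips")
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    if max(depths) <= 0:
        raise ParseError("zero-length tree: no positive root-to-tip path")
    if any(d <= 0 for d in depths):
        raise ParseError("every tip must have positive root-to-tip path length")
    return tree


@dataclasses.dataclass
class PipelineConfig:
    """Paths, filter thresholds and reproducibility settings for a full run.

    The season window defaults to the standard spring ringing period
    (16 April – 15 May).
    """

    captures: str | None = None
    effort: str | None = None
    descriptors: str | None = None
    traits: str | None = None
    abundance: str | None = None
    tree: str | None = None
    outdir: str = "stopover_results"
    season_start: str = "04-16"
    season_end: str = "05-15"
    min_years: int = 5
    min_islands: int = 5
    min_days_per_fortnight: int = 7
    n_permutations: int = 999
    seed: int = 0
    vif_threshold: float = 10.0
    excluded_islands: tuple[str, ...] = ("Columbrets",)

    def __post_init__(self) -> None:
        if self.n_permutations < 99:
            raise ValueError(
                f"n_permutations must be >= 99 (got {self.n_permutations})"
            )
        if self.min_days_per_fortnight < 1:
            raise ValueError("min_days_per_fortnight must be >= 1")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "excluded_islands" in raw:
        raw["excluded_islands"] = tuple(raw["excluded_islands"])
    return PipelineConfig(**raw)


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=index, float_format="%.10g")
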