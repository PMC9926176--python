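"""Occurrence-record ingestion: cleaning, deduplication, basin assignment,
and intersection with the phylogeny.

Cleaning mirrors the usual museum/GBIF hygiene pass: coordinate validation,
synonym resolution against an accepted-names map, removal of exotic
species, and a rejection log with machine-readable reason codes. Every
output row traces to an input row; nothing is invented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .basins import BasinHierarchy
from .trees import prune_to_taxa

__all__ = [
    "CleaningTables",
    "read_occurrences",
    "write_occurrences",
    "clean_occurrences",
    "unique_records",
    "assign_to_basins",
    "intersect_with_tree",
]

COLUMNS = ["species", "lon", "lat", "date", "basin_id", "source"]

#: decimals used when comparing coordinates in the uniqueness key (~11 m)
COORD_DECIMALS = 4


@dataclass
class CleaningTables:
    """Name-validation side tables: synonym map and exotic-species list."""

    synonym_map: dict[str, str] = field(default_factory=dict)
    exotic_list: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for raw, acc in self.synonym_map.items():
            resolved = self.synonym_map.get(acc, acc)
            if resolved != acc:
                raise ValueError(
                    f"synonym map is not idempotent: {raw!r} -> {acc!r} -> {resolved!r}"
                )

    def resolve(self, name: str) -> str:
        return self.synonym_map.get(name, name)


def read_occurrences(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # report offending line
        raise OSError(f"malformed occurrence CSV {path}: {exc}") from exc
    missing = {"species", "lon", "lat"} - set(df.columns)
    if missing:
        raise OSError(f"occurrence CSV {path} lacks columns: {sorted(missing)}")
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = ""
    return df[COLUMNS]


def write_occurrences(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def clean_occurrences(
    raw: pd.DataFrame, tables: CleaningTables | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Validate and normalize records; return (clean table, rejection log).

    Rejection reasons: ``empty_species``, ``coordinate_unparseable``,
    ``coordinate_out_of_range``, ``exotic_species``. The clean row count
    plus the rejection count always equals the input count.
    """
    tables = tables or CleaningTables()
    df = raw.copy().reset_index(drop=True)
    for col in COLUMNS:
        if col not in df.columns:
            df[col] = ""
    reasons = pd.Series("", index=df.index, dtype=object)

    species = df["species"].astype(str).str.strip().str.replace(r"\s+", " ", regex=True)
    reasons[species == ""] = "empty_species"

    lon = pd.to_numeric(df["lon"], errors="coerce")
    lat = pd.to_numeric(df["lat"], errors="coerce")
    bad_parse = (lon.isna() | lat.isna()) & (reasons == "")
    reasons[bad_parse] = "coordinate_unparseable"
    out_of_range = (
        (lon < -180) | (lon > 180) | (lat < -90) | (lat > 90)
    ).fillna(False) & (reasons == "")
    reasons[out_of_range] = "coordinate_out_of_range"

    species = species.map(tables.resolve)
    reasons[(species.isin(tables.exotic_list)) & (reasons == "")] = "exotic_species"

    keep = reasons == ""
    clean = df.loc[keep].copy()
    clean["species"] = species[keep]
    clean["lon"] = lon[keep]
    clean["lat"] = lat[keep]
    clean["date"] = clean["date"].astype(str).str.strip()
    rejects = df.loc[~keep].copy()
    rejects["reason"] = reasons[~keep]
    return clean.reset_index(drop=True), rejects.reset_index(drop=True)


def unique_records(table: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """One row per (species, rounded coordinates, sampling date) combination.

    Coordinates are compared at 4 decimal places; missing dates participate
    as the distinct value ``unknown`` (conservative: keeps records apart).
    Returns the deduplicated table and the number of rows removed.
    """
    df = table.copy()
    key_date = df["date"].astype(str).str.strip().replace("", "unknown").fillna("unknown")
    key = pd.DataFrame(
        {
            "species": df["species"],
            "lon": np.round(df["lon"].astype(float), COORD_DECIMALS),
            "lat": np.round(df["lat"].astype(float), COORD_DECIMALS),
            "date": key_date,
        }
    )
    keep = ~key.duplicated()
    return df.loc[keep].reset_index(drop=True), int((~keep).sum())


def assign_to_basins(
    table: pd.DataFrame, hierarchy: BasinHierarchy
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attach a level-5 basin id to every record; reject points in no basin.

    Records carrying a valid pre-assigned ``basin_id`` keep it (the real-data
    path: the spatial join was done upstream in GIS). Otherwise the point is
    located in the hierarchy's box footprints, which must not overlap.
    """
    df = table.copy().reset_index(drop=True)
    known = set(hierarchy.basin_ids)
    footprints = hierarchy.footprints
    if footprints:
        items = list(footprints.items())
        ids = [b for b, _ in items]
        boxes = np.array([f for _, f in items])  # lon0 lat0 lon1 lat1
        for i in range(len(items)):
            ov = (
                (boxes[:, 0] < boxes[i, 2]) & (boxes[:, 2] > boxes[i, 0])
                & (boxes[:, 1] < boxes[i, 3]) & (boxes[:, 3] > boxes[i, 1])
            )
            ov[i] = False
            if ov.any():
                j = int(np.flatnonzero(ov)[0])
                raise ValueError(f"overlapping basin footprints: {ids[i]} and {ids[j]}")

    assigned = []
    reasons = []
    for _, row in df.iterrows():
        bid = str(row.get("basin_id", "") or "")
        if bid in known:
            assigned.append(bid)
            reasons.append("")
            continue
        hit = ""
        if footprints:
            lon, lat = float(row["lon"]), float(row["lat"])
            for b, (lon0, lat0, lon1, lat1) in footprints.items():
                if lon0 <= lon < lon1 and lat0 <= lat < lat1:
                    hit = b
                    break
        assigned.append(hit)
        reasons.append("" if hit else "no_basin")
    df["basin_id"] = assigned
    rej = pd.Series(reasons, index=df.index)
    rejects = df.loc[rej != ""].copy()
    rejects["reason"] = "no_basin"
    return df.loc[rej == ""].reset_index(drop=True), rejects.reset_index(drop=True)


def intersect_with_tree(
    table: pd.DataFrame, tree: dendropy.Tree
) -> tuple[dendropy.Tree, pd.DataFrame, dict]:
    """Prune the tree to recorded species and drop records off the tree.

    Returns (pruned tree, filtered table, counts). Errors if the species
    sets are disjoint.
    """
    table_species = set(table["species"].unique())
    tree_species = {t.label for t in tree.taxon_namespace}
    shared = table_species & tree_species
    if not shared:
        raise ValueError("occurrence table and tree share no species")
    pruned = prune_to_taxa(tree, shared)
    filtered = table[table["species"].isin(shared)].reset_index(drop=True)
    counts = {
        "species_in_table": len(table_species),
        "species_on_tree": len(tree_species),
        "species_shared": len(shared),
        "records_in": int(len(table)),
        "records_out": int(len(filtered)),
    }
    return pruned, filtered, counts
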