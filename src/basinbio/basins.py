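"""Nested drainage-basin hierarchy: level-5 units inside level-4 catchments inside bioregions.

Level-5 basins sharing a level-4 parent are mutually "adjacent" — they form
the neighbor pool used when gap-filling an under-sampled focal basin.
Footprints are abstract axis-aligned lon/lat boxes used only to exercise the
coordinate-based cleaning and assignment logic of synthetic data; real data
arrive with a pre-assigned basin id instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd


@dataclass
class BasinHierarchy:
    """Nested spatial units with surface areas and within-level-4 adjacency.

    ``table`` has one row per level-5 basin with columns
    ``basin_id, level4_id, bioregion_id, area_km2``.
    ``footprints`` maps basin_id -> (lon_min, lat_min, lon_max, lat_max);
    it may be empty for real data where basin ids are supplied directly.
    """

    table: pd.DataFrame
    footprints: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"basin_id", "level4_id", "bioregion_id", "area_km2"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"basin table missing columns: {sorted(missing)}")
        if self.table["basin_id"].duplicated().any():
            raise ValueError("duplicate basin_id in basin table")
        if (self.table["area_km2"] <= 0).any():
            raise ValueError("basin areas must be positive")
        self.table = self.table.reset_index(drop=True)
        self._level4 = dict(zip(self.table["basin_id"], self.table["level4_id"]))
        self._bioregion = dict(zip(self.table["basin_id"], self.table["bioregion_id"]))
        self._area = dict(zip(self.table["basin_id"], self.table["area_km2"]))
        self._siblings: dict[str, list[str]] = {}
        for _, grp in self.table.groupby("level4_id", sort=False):
            ids = list(grp["basin_id"])
            for b in ids:
                self._siblings[b] = [x for x in ids if x != b]

    @property
    def basin_ids(self) -> list[str]:
        return list(self.table["basin_id"])

    @property
    def bioregion_ids(self) -> list[str]:
        return list(pd.unique(self.table["bioregion_id"]))

    def level4_of(self, basin_id: str) -> str:
        return self._level4[basin_id]

    def bioregion_of(self, basin_id: str) -> str:
        return self._bioregion[basin_id]

    def area_of(self, basin_id: str) -> float:
        return float(self._area[basin_id])

    def neighbors(self, basin_id: str) -> list[str]:
        """Level-5 basins sharing this basin's level-4 catchment (adjacency pool)."""
        return list(self._siblings[basin_id])

    def areas(self) -> pd.Series:
        return self.table.set_index("basin_id")["area_km2"].astype(float)

    def basins_of_bioregion(self, bioregion_id: str) -> list[str]:
        sel = self.table["bioregion_id"] == bioregion_id
        return list(self.table.loc[sel, "basin_id"])

    # ------------------------------------------------------------------ IO

    def to_frame(self) -> pd.DataFrame:
        """Flat table including footprint columns and the neighbor list."""
        df = self.table.copy()
        if self.footprints:
            for i, col in enumerate(["lon_min", "lat_min", "lon_max", "lat_max"]):
                df[col] = [self.footprints[b][i] for b in df["basin_id"]]
        df["neighbors"] = [";".join(self.neighbors(b)) for b in df["basin_id"]]
        return df

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_csv(cls, path) -> "BasinHierarchy":
        df = pd.read_csv(path, dtype={"basin_id": str, "level4_id": str, "bioregion_id": str})
        footprints: dict[str, tuple[float, float, float, float]] = {}
        if {"lon_min", "lat_min", "lon_max", "lat_max"} <= set(df.columns):
            for _, row in df.iterrows():
                footprints[row["basin_id"]] = (
                    float(row["lon_min"]), float(row["lat_min"]),
                    float(row["lon_max"]), float(row["lat_max"]),
                )
        cols = ["basin_id", "level4_id", "bioregion_id", "area_km2"]
        out = df[cols].copy()
        out["area_km2"] = out["area_km2"].astype(float)
        return cls(out, footprints)
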