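"""The study-shaped sampling design: 22 sites, 11 locations, 3 regions.

Coordinates are rough colony positions bundled purely so that between-
location distances (~100 km accuracy) can be computed for IBD tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ..popgen.ibd import GeoTable
from ..popgen.partition import PopulationPartition

# subspecies, location, site, site_code, n_mt, n_nuclear, lat, lon
_TABLE1_ROWS = [
    ("kaiurka", "Andr", "Tn", 4, 3, 51.95, -176.00),
    ("kaiurka", "Andr", "Gs", 2, 1, 52.07, -176.13),
    ("kaiurka", "Andr", "Ad", 4, 5, 51.85, -176.65),
    ("adianta", "Fox", "Aa", 1, 1, 52.99, -168.90),
    ("adianta", "Fox", "Un", 2, 2, 53.72, -166.80),
    ("adianta", "Fox", "Ai", 5, 4, 54.18, -164.85),
    ("adianta", "Shum", "Be", 3, 3, 55.10, -162.05),
    ("adianta", "Shum", "Yu", 4, 4, 55.07, -159.52),
    ("adianta", "Semi", "Se", 4, 5, 56.10, -156.70),
    ("adianta", "Semi", "Fl", 3, 5, 55.92, -156.47),
    ("adianta", "Cook", "Sh", 2, 3, 58.55, -152.50),
    ("adianta", "Cook", "Ka", 32, 30, 59.60, -151.40),
    ("adianta", "PWS", "Ja", 12, 12, 60.33, -148.15),
    ("adianta", "PWS", "Nk", 18, 17, 60.65, -147.40),
    ("adianta", "SEAK", "Mi", 6, 6, 57.83, -133.70),
    ("adianta", "SEAK", "Cv", 3, 3, 58.19, -135.06),
    ("adianta", "WVan", "Cl", 7, 9, 49.17, -126.09),
    ("adianta", "SGeo", "Ma", 29, 29, 48.63, -123.28),
    ("eureka", "cOre", "Co", 24, 23, 43.37, -124.32),
    ("eureka", "cCal", "PR", 1, 1, 38.00, -123.02),
    ("eureka", "cCal", "SF", 34, 28, 37.70, -123.00),
    ("eureka", "cCal", "AN", 2, 0, 37.11, -122.34),
]

#: location -> pooled region used by the demographic analysis
LOCATION_REGION = {
    "Andr": "Aleutians",
    "Fox": "Aleutians",
    "Shum": "Central",
    "Semi": "Central",
    "Cook": "Central",
    "PWS": "Central",
    "SEAK": "Central",
    "WVan": "South",
    "SGeo": "South",
    "cOre": "South",
    "cCal": "South",
}


@dataclass
class SamplingDesign:
    """Per-site sample counts with the location/region/subspecies nesting."""

    table: pd.DataFrame  # columns: subspecies, location_code, site_code,
    # n_mt, n_nuclear, lat, lon, region

    def __post_init__(self) -> None:
        required = {
            "subspecies", "location_code", "site_code",
            "n_mt", "n_nuclear", "lat", "lon", "region",
        }
        if required - set(self.table.columns):
            raise ValueError("design table missing columns")
        if self.table["site_code"].duplicated().any():
            raise ValueError("duplicate site codes")

    @property
    def n_mt_total(self) -> int:
        return int(self.table["n_mt"].sum())

    @property
    def n_nuclear_total(self) -> int:
        return int(self.table["n_nuclear"].sum())

    @property
    def n_sites(self) -> int:
        return len(self.table)

    @property
    def locations(self) -> list[str]:
        return list(dict.fromkeys(self.table["location_code"]))

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.table["region"]))

    def region_sizes(self, marker: str = "mt") -> dict[str, int]:
        col = "n_mt" if marker == "mt" else "n_nuclear"
        sums = self.table.groupby("region", sort=False)[col].sum()
        return {str(k): int(v) for k, v in sums.items()}

    def partition(self, marker: str = "mt") -> PopulationPartition:
        """One row per individual, ids like ``Ka01``; region-major order
        matches the simulator's tip layout (Aleutians, Central, South)."""
        col = "n_mt" if marker == "mt" else "n_nuclear"
        ids, sites, locs, regions, subs = [], [], [], [], []
        for region in ("Aleutians", "Central", "South"):
            sub = self.table[self.table["region"] == region]
            for row in sub.itertuples():
                count = int(getattr(row, col))
                for i in range(count):
                    ids.append(f"{row.site_code}{i + 1:02d}")
                    sites.append(row.site_code)
                    locs.append(row.location_code)
                    regions.append(region)
                    subs.append(row.subspecies)
        return PopulationPartition(ids, sites, locs, regions, subs)

    def geo_table(self) -> GeoTable:
        return GeoTable(
            self.table["site_code"].tolist(),
            self.table["lat"].to_numpy(float),
            self.table["lon"].to_numpy(float),
        )


def table1_design() -> SamplingDesign:
    """The published 202-mtDNA / 194-nuclear sampling layout."""
    df = pd.DataFrame(
        _TABLE1_ROWS,
        columns=[
            "subspecies", "location_code", "site_code",
            "n_mt", "n_nuclear", "lat", "lon",
        ],
    )
    df["region"] = df["location_code"].map(LOCATION_REGION)
    return SamplingDesign(df)
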