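"""Isolation-by-distance machinery: linearized F_ST, great-circle
geography, Mantel permutation tests, and Benjamini-Yekutieli thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .partition import PopulationPartition

EARTH_RADIUS_KM = 6371.0


def slatkin_linearize(f: float) -> float:
    """Slatkin's linearization f/(1-f); negative estimates clamp to 0 first."""
    if f >= 1.0:
        raise ValueError("linearization undefined at f = 1")
    f = max(f, 0.0)
    return f / (1.0 - f)


def by_adjust(alpha: float, m: int) -> float:
    """Benjamini-Yekutieli threshold alpha / sum_{i=1}^m 1/i for m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / float(np.sum(1.0 / np.arange(1, m + 1)))


@dataclass
class GeoTable:
    """Per-site decimal-degree coordinates."""

    site_codes: list[str]
    lat: np.ndarray
    lon: np.ndarray

    def __post_init__(self) -> None:
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        if len(self.site_codes) != len(self.lat) or len(self.lat) != len(self.lon):
            raise ValueError("site/lat/lon length mismatch")
        if (np.abs(self.lat) > 90).any():
            raise ValueError("latitude out of range")
        if (np.abs(self.lon) > 180).any():
            raise ValueError("longitude out of range")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_code": self.site_codes, "lat": self.lat, "lon": self.lon}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GeoTable":
        required = {"site_code", "lat", "lon"}
        if required - set(df.columns):
            raise ValueError("coords table needs site_code, lat, lon")
        return cls(
            df["site_code"].astype(str).tolist(),
            df["lat"].to_numpy(float),
            df["lon"].to_numpy(float),
        )


def _to_unit_xyz(lat: np.ndarray, lon: np.ndarray) -> np.ndarray:
    la, lo = np.radians(lat), np.radians(lon)
    return np.column_stack(
        [np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)]
    )


def great_circle_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance on a sphere of radius 6371 km."""
    a = _to_unit_xyz(np.atleast_1d(lat1), np.atleast_1d(lon1))
    b = _to_unit_xyz(np.atleast_1d(lat2), np.atleast_1d(lon2))
    dot = np.clip((a * b).sum(axis=1), -1.0, 1.0)
    return float(EARTH_RADIUS_KM * np.arccos(dot)[0])


def location_midpoints(
    geo: GeoTable, partition: PopulationPartition
) -> pd.DataFrame:
    """Midpoint (3-D centroid re-normalized to the sphere) per location.

    Locations are weighted by their member sites, not by sample counts.
    """
    site_loc: dict[str, str] = {}
    for s, l in zip(partition.site, partition.location):
        site_loc[s] = l
    missing = [s for s in site_loc if s not in set(geo.site_codes)]
    if missing:
        raise ValueError(f"sites without coordinates: {sorted(missing)}")
    xyz = _to_unit_xyz(geo.lat, geo.lon)
    pos = {s: i for i, s in enumerate(geo.site_codes)}
    rows = []
    for loc in dict.fromkeys(partition.location):
        sites = [s for s, l in site_loc.items() if l == loc]
        centroid = xyz[[pos[s] for s in sites]].mean(axis=0)
        norm = np.linalg.norm(centroid)
        if norm == 0:
            raise ValueError(f"degenerate midpoint for location {loc!r}")
        c = centroid / norm
        lat = float(np.degrees(np.arcsin(np.clip(c[2], -1, 1))))
        lon = float(np.degrees(np.arctan2(c[1], c[0])))
        rows.append((loc, lat, lon))
    return pd.DataFrame(rows, columns=["location_code", "lat", "lon"])


def geo_distance_matrix(
    geo: GeoTable, partition: PopulationPartition
) -> pd.DataFrame:
    """Great-circle km between location midpoints (symmetric, zero diag)."""
    mid = location_midpoints(geo, partition)
    xyz = _to_unit_xyz(mid["lat"].to_numpy(), mid["lon"].to_numpy())
    dot = np.clip(xyz @ xyz.T, -1.0, 1.0)
    km = EARTH_RADIUS_KM * np.arccos(dot)
    np.fill_diagonal(km, 0.0)
    return pd.DataFrame(km, index=mid["location_code"], columns=mid["location_code"])


@dataclass
class MantelResult:
    r: float
    p: float | None
    n_perm: int
    n: int = field(default=0)


def _upper(mat: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(mat.shape[0], k=1)
    return mat[iu]


def mantel(
    A: np.ndarray | pd.DataFrame,
    B: np.ndarray | pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal upper triangles; the
    p-value permutes rows and columns of B simultaneously, one-sided for
    positive association, p = (b+1)/(B+1).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrices must be square and same shape")
    n = A.shape[0]
    if n < 4:
        raise ValueError("Mantel test needs at least 4 units")
    for M, name in ((A, "A"), (B, "B")):
        if not np.allclose(M, M.T):
            raise ValueError(f"matrix {name} not symmetric")
        if not np.allclose(np.diag(M), 0):
            raise ValueError(f"matrix {name} diagonal not zero")
    a = _upper(A)
    if a.std() == 0 or _upper(B).std() == 0:
        raise ValueError("zero variance in a distance matrix")
    a_center = a - a.mean()
    a_denom = np.sqrt(np.sum(a_center**2))

    def corr(mat_b: np.ndarray) -> float:
        b_vec = _upper(mat_b)
        b_center = b_vec - b_vec.mean()
        denom = a_denom * np.sqrt(np.sum(b_center**2))
        if denom == 0:
            return 0.0
        return float(np.sum(a_center * b_center) / denom)

    r_obs = corr(B)
    p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        b_count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            if corr(B[np.ix_(perm, perm)]) >= r_obs - 1e-12:
                b_count += 1
        p = (b_count + 1) / (n_perm + 1)
    return MantelResult(r_obs, p, n_perm, n)
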