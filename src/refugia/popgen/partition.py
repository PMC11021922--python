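"""Nested sample -> site -> location -> region labelling."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REGIONS = ("Aleutians", "Central", "South")


@dataclass
class PopulationPartition:
    """Per-sample hierarchical population labels.

    Every sample belongs to exactly one site, which belongs to one location,
    which belongs to one region; regions must partition locations.
    """

    sample_ids: list[str]
    site: list[str]
    location: list[str]
    region: list[str]
    subspecies: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if not self.subspecies:
            self.subspecies = [""] * n
        for name in ("site", "location", "region", "subspecies"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} labels do not match sample count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids in partition")
        # sites nest in locations, locations nest in regions
        for child, parent in (("site", "location"), ("location", "region")):
            seen: dict[str, str] = {}
            for c, p in zip(getattr(self, child), getattr(self, parent)):
                if seen.setdefault(c, p) != p:
                    raise ValueError(
                        f"{child} {c!r} assigned to multiple {parent}s"
                    )

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def labels(self, level: str) -> np.ndarray:
        if level not in ("site", "location", "region", "subspecies"):
            raise ValueError(f"unknown level {level!r}")
        return np.asarray(getattr(self, level))

    def group_indices(self, level: str) -> dict[str, np.ndarray]:
        """Sample indices per group at the requested level, insertion-ordered."""
        lab = self.labels(level)
        out: dict[str, np.ndarray] = {}
        for g in dict.fromkeys(lab.tolist()):
            out[g] = np.flatnonzero(lab == g)
        return out

    def subset(self, indices) -> "PopulationPartition":
        idx = list(indices)
        return PopulationPartition(
            [self.sample_ids[i] for i in idx],
            [self.site[i] for i in idx],
            [self.location[i] for i in idx],
            [self.region[i] for i in idx],
            [self.subspecies[i] for i in idx],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "site_code": self.site,
                "location_code": self.location,
                "region": self.region,
                "subspecies": self.subspecies,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PopulationPartition":
        required = {"sample_id", "site_code", "location_code", "region"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"popmap missing columns: {sorted(missing)}")
        sub = (
            df["subspecies"].astype(str).tolist()
            if "subspecies" in df.columns
            else []
        )
        return cls(
            df["sample_id"].astype(str).tolist(),
            df["site_code"].astype(str).tolist(),
            df["location_code"].astype(str).tolist(),
            df["region"].astype(str).tolist(),
            sub,
        )
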