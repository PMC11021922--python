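"""Reference tables: (scenario, parameter draw, summary vector) rows."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..scenarios.events import ALL_PARAMS, build_scenario, sample_parameters
from ..scenarios.mutation import MutationModel
from ..scenarios.priors import PriorSet
from ..scenarios.simulate import DEFAULT_REGION_SIZES, simulate_dataset
from .sumstats import flag_names, stat_names, summary_vector

PARAM_COLUMNS = [f"param_{p}" for p in ALL_PARAMS]


@dataclass
class ReferenceTable:
    """Simulation table plus per-statistic robust scales (MAD).

    Parameter columns not used by a row's scenario are NaN.  Columns whose
    MAD is zero get scale 1 (with a warning at construction).
    """

    df: pd.DataFrame
    mad: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        needed = ["scenario", *stat_names()]
        missing = [c for c in needed if c not in self.df.columns]
        if missing:
            raise ValueError(f"reference table missing columns: {missing}")
        if self.df["scenario"].nunique() < 2:
            raise ValueError("model choice needs >= 2 scenarios in the table")
        if self.mad is None:
            self.mad = self._compute_mad()

    def _compute_mad(self) -> np.ndarray:
        stats = self.stats
        med = np.median(stats, axis=0)
        mad = np.median(np.abs(stats - med), axis=0)
        degenerate = mad == 0
        if degenerate.any():
            cols = [stat_names()[i] for i in np.flatnonzero(degenerate)]
            warnings.warn(
                f"degenerate summary-statistic columns (MAD=0), scale set "
                f"to 1: {cols}",
                stacklevel=2,
            )
            mad = np.where(degenerate, 1.0, mad)
        return mad

    @property
    def n_rows(self) -> int:
        return len(self.df)

    @property
    def scenarios(self) -> list[int]:
        return sorted(self.df["scenario"].unique().tolist())

    @property
    def stats(self) -> np.ndarray:
        return self.df[stat_names()].to_numpy(float)

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        return cls(pd.read_csv(path))


def build_reference_table(
    scenario_ids=(1, 2, 3),
    priors: PriorSet | None = None,
    n_per_scenario: int = 10_000,
    region_sizes: dict[str, int] | None = None,
    model: MutationModel | None = None,
    seed: int | None = None,
) -> ReferenceTable:
    """Simulate a balanced reference table, reproducible given the seed."""
    if n_per_scenario < 100:
        raise ValueError("n_per_scenario must be >= 100")
    priors = priors or PriorSet()
    model = model or MutationModel()
    region_sizes = dict(region_sizes or DEFAULT_REGION_SIZES)
    rng = np.random.default_rng(seed)
    rows = []
    snames = stat_names()
    fnames = flag_names()
    for sid in scenario_ids:
        scenario = build_scenario(sid)
        for _ in range(n_per_scenario):
            params = sample_parameters(scenario, priors, rng)
            ds = simulate_dataset(
                scenario, params, region_sizes, model, priors, rng
            )
            vec = summary_vector(ds.alignment, ds.partition)
            row: dict[str, float] = {"scenario": sid}
            for p in ALL_PARAMS:
                row[f"param_{p}"] = params.get(p, np.nan)
            row.update(dict(zip(snames, vec.values)))
            row.update(dict(zip(fnames, vec.d_undefined.astype(int))))
            rows.append(row)
    df = pd.DataFrame(rows)
    return ReferenceTable(df)
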