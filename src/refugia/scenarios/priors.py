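"""Uniform priors over demographic parameters.

All population sizes are in gene copies of the simulated (haploid,
maternally inherited) locus; times are in generations before present.
Deep times (t2, tc) pre-date the shallow window (t1, ta, tb) by
construction of disjoint ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GENERATION_TIME_YEARS = 8.8


@dataclass(frozen=True)
class PriorSet:
    ne_low: float = 10.0
    ne_high: float = 100_000.0
    deep_low: float = 1250.0  # t2, tc (generations)
    deep_high: float = 100_000.0
    shallow_low: float = 0.0  # t1, ta, tb (generations)
    shallow_high: float = 1250.0
    ra_low: float = 0.001
    ra_high: float = 0.999
    generation_time_years: float = GENERATION_TIME_YEARS

    def __post_init__(self) -> None:
        if self.ne_low <= 0 or self.ne_high < self.ne_low:
            raise ValueError("invalid N_e bounds")
        if self.deep_low < self.shallow_high:
            raise ValueError("deep-time lower bound must be >= shallow upper bound")
        if not 0 < self.ra_low <= self.ra_high < 1:
            raise ValueError("invalid admixture-rate bounds")

    def as_dict(self) -> dict:
        return {
            "ne": [self.ne_low, self.ne_high],
            "deep_time": [self.deep_low, self.deep_high],
            "shallow_time": [self.shallow_low, self.shallow_high],
            "ra": [self.ra_low, self.ra_high],
            "generation_time_years": self.generation_time_years,
        }


def mutation_rate_per_generation(
    divergence_rate_per_my: float = 0.074,
    generation_time_years: float = GENERATION_TIME_YEARS,
) -> float:
    """Per-site per-generation rate from a per-lineage %/My divergence rate.

    0.074/My per site * 8.8 y/generation = 6.5e-7.
    """
    return divergence_rate_per_my / 1e6 * generation_time_years


def generations_to_years(
    generations: float, generation_time_years: float = GENERATION_TIME_YEARS
) -> float:
    return generations * generation_time_years
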