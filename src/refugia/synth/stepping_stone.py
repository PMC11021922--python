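"""Forward Wright-Fisher gene-flow fixtures: linear stepping-stone vs island.

Biallelic loci evolve as allele frequencies under binomial drift with
migration to nearest neighbours (linear) or uniformly to all demes
(island).  Demes sit equidistantly on a line so a geographic distance
matrix is well defined; the linear topology should show isolation by
distance, the island topology should not.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..popgen.genotypes import GenotypeTable
from ..popgen.ibd import GeoTable
from ..popgen.partition import PopulationPartition


@dataclass
class SteppingStoneBundle:
    genotypes: GenotypeTable
    partition: PopulationPartition
    geo: GeoTable
    allele_freqs: np.ndarray  # (n_demes, n_loci) final frequencies
    topology: str


def _migration_step(p: np.ndarray, m: float, topology: str) -> np.ndarray:
    if topology == "island":
        n = p.shape[0]
        mean_others = (p.sum(axis=0, keepdims=True) - p) / (n - 1)
        return (1 - m) * p + m * mean_others
    out = p.copy() * (1 - m)
    out[0] = (1 - m / 2) * p[0]
    out[-1] = (1 - m / 2) * p[-1]
    out[1:] += (m / 2) * p[:-1]
    out[:-1] += (m / 2) * p[1:]
    return out


def stepping_stone_fixture(
    n_demes: int = 10,
    N_per_deme: int = 200,
    m: float = 0.05,
    topology: str = "linear",
    n_loci: int = 20,
    n_generations: int = 500,
    sample_size: int = 20,
    seed: int | None = None,
    deme_spacing_deg: float = 1.0,
) -> SteppingStoneBundle:
    """Simulate diploid genotypes under restricted or uniform gene flow.

    All loci start at frequency 0.5; after ``n_generations`` of
    migration-then-drift, ``sample_size`` diploids per deme are drawn by
    binomial sampling from the final frequencies.
    """
    if n_demes < 4:
        raise ValueError("need at least 4 demes")
    if not 0 < m < 0.5:
        raise ValueError("migration rate must be in (0, 0.5)")
    if topology not in ("linear", "island"):
        raise ValueError("topology must be 'linear' or 'island'")
    if N_per_deme < 2 or n_loci < 1 or n_generations < 1 or sample_size < 2:
        raise ValueError("invalid simulation size parameter")
    rng = np.random.default_rng(seed)
    two_n = 2 * N_per_deme
    p = np.full((n_demes, n_loci), 0.5)
    for _ in range(n_generations):
        p = _migration_step(p, m, topology)
        p = rng.binomial(two_n, p) / two_n

    deme_names = [f"D{i + 1:02d}" for i in range(n_demes)]
    sample_ids, sites = [], []
    for d in deme_names:
        for i in range(sample_size):
            sample_ids.append(f"{d}_{i + 1:02d}")
            sites.append(d)
    partition = PopulationPartition(
        sample_ids, sites, sites[:], ["all"] * len(sites)
    )
    calls: dict[str, np.ndarray] = {}
    for l in range(n_loci):
        draws = rng.random((n_demes, sample_size, 2))
        alleles = (draws < p[:, l, None, None]).astype(int)
        arr = alleles.reshape(-1, 2).astype(str).astype(object)
        calls[f"L{l + 1:02d}"] = arr
    genotypes = GenotypeTable(sample_ids, calls)
    geo = GeoTable(
        deme_names,
        np.zeros(n_demes),
        np.arange(n_demes, dtype=float) * deme_spacing_deg,
    )
    return SteppingStoneBundle(genotypes, partition, geo, p, topology)
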