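"""Full synthetic study bundles: mtDNA alignment plus nuclear genotypes."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .. import io as rio
from ..popgen.alignment import SequenceAlignment
from ..popgen.genotypes import MISSING_ALLELE, GenotypeTable
from ..popgen.ibd import GeoTable
from ..popgen.partition import PopulationPartition
from ..scenarios.coalescent import Genealogy, simulate_genealogy
from ..scenarios.events import build_scenario, sample_parameters
from ..scenarios.mutation import MutationModel, evolve_sequences
from ..scenarios.priors import PriorSet
from ..scenarios.simulate import REGION_NAMES
from .design import SamplingDesign, table1_design

MICROSAT_LOCI = ("Dpu16", "Uaa5-8", "Cco5-9", "Cco5-21")
INTRON_LOCI = ("CytC-I", "RP40-V")
MICROSAT_RATE = 5e-4  # per gene copy per generation, single-step symmetric
INTRON_RATE = 2e-6  # per locus per generation, infinite sites
MICROSAT_ROOT_REPEAT = 20
#: nuclear gene copies outnumber mtDNA copies; synthetic loci scale N by this
NUCLEAR_NE_FACTOR = 4.0


@dataclass
class StudyBundle:
    alignment: SequenceAlignment
    partition: PopulationPartition  # mtDNA individuals
    genotypes: GenotypeTable
    nuclear_partition: PopulationPartition
    geo: GeoTable
    metadata: dict

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "study.fasta",
            "popmap": outdir / "popmap.tsv",
            "nuclear_popmap": outdir / "popmap_nuclear.tsv",
            "coords": outdir / "coords.tsv",
            "genotypes": outdir / "genotypes.tsv",
            "metadata": outdir / "metadata.json",
        }
        rio.write_fasta(self.alignment, paths["fasta"])
        rio.write_popmap(self.partition, paths["popmap"])
        rio.write_popmap(self.nuclear_partition, paths["nuclear_popmap"])
        rio.write_coords(self.geo, paths["coords"])
        rio.write_genotypes(self.genotypes, paths["genotypes"])
        rio.write_json(self.metadata, paths["metadata"])
        return paths


def _region_tip_counts(design: SamplingDesign, marker: str) -> dict[str, int]:
    sizes = design.region_sizes(marker)
    out = {}
    for key, name in REGION_NAMES.items():
        if sizes.get(name, 0) > 0:
            out[key] = sizes[name]
    return out


def _microsat_alleles(
    genealogy: Genealogy, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Stepwise-mutation repeat counts at the tips."""
    n = genealogy.n_tips
    values = np.zeros(2 * n - 1, dtype=int)
    values[genealogy.root] = MICROSAT_ROOT_REPEAT
    for internal in range(genealogy.root, n - 1, -1):
        for child in genealogy.children[internal - n]:
            child = int(child)
            t = genealogy.time[internal] - genealogy.time[child]
            steps = rng.poisson(rate * t)
            net = int(rng.binomial(steps, 0.5) * 2 - steps) if steps else 0
            values[child] = values[internal] + net
    return np.maximum(values[:n], 2)  # repeat count floor


def _intron_alleles(
    genealogy: Genealogy, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Infinite-sites haplotype ids at the tips."""
    n = genealogy.n_tips
    muts: list[frozenset[int]] = [frozenset()] * (2 * n - 1)
    next_mut = 0
    for internal in range(genealogy.root, n - 1, -1):
        for child in genealogy.children[internal - n]:
            child = int(child)
            t = genealogy.time[internal] - genealogy.time[child]
            m = rng.poisson(rate * t)
            new = frozenset(range(next_mut, next_mut + m))
            next_mut += m
            muts[child] = muts[internal] | new
    tip_sets = muts[:n]
    uniq = {s: i for i, s in enumerate(dict.fromkeys(tip_sets))}
    return np.array([uniq[s] for s in tip_sets])


def generate_study(
    scenario_id: int = 1,
    params: dict[str, float] | None = None,
    design: SamplingDesign | None = None,
    model: MutationModel | None = None,
    priors: PriorSet | None = None,
    seed: int | None = None,
) -> StudyBundle:
    """Simulate a complete study-shaped bundle under one scenario.

    mtDNA sequences come from the scenario coalescent + HKY+I+G; four
    microsatellites (stepwise model) and two introns (infinite sites) are
    simulated on independent gene trees from the same demographic history
    with nuclear-scaled population sizes, then paired into diploids.
    """
    design = design or table1_design()
    model = model or MutationModel()
    priors = priors or PriorSet()
    rng = np.random.default_rng(seed)
    scenario = build_scenario(scenario_id)
    if params is None:
        params = sample_parameters(scenario, priors, rng)

    # mtDNA
    mt_counts = _region_tip_counts(design, "mt")
    genealogy = simulate_genealogy(scenario, params, mt_counts, rng)
    alignment = evolve_sequences(genealogy, model, rng)
    partition = design.partition("mt")
    alignment = SequenceAlignment(list(partition.sample_ids), alignment.sequences)

    # nuclear loci on scaled demography, two gene copies per individual
    nuc_partition = design.partition("nuclear")
    nuc_counts = {k: 2 * v for k, v in _region_tip_counts(design, "nuclear").items()}
    nuc_params = {
        k: (v * NUCLEAR_NE_FACTOR if k.startswith("N_") else v)
        for k, v in params.items()
    }
    n_ind = nuc_partition.n
    calls: dict[str, np.ndarray] = {}
    for locus in MICROSAT_LOCI + INTRON_LOCI:
        g = simulate_genealogy(scenario, nuc_params, nuc_counts, rng)
        if locus in MICROSAT_LOCI:
            alleles = _microsat_alleles(g, MICROSAT_RATE, rng).astype(str)
        else:
            alleles = np.char.add("a", _intron_alleles(g, INTRON_RATE, rng).astype(str))
        arr = np.full((n_ind, 2), MISSING_ALLELE, dtype=object)
        arr[:, 0] = alleles[0::2]
        arr[:, 1] = alleles[1::2]
        calls[locus] = arr
    genotypes = GenotypeTable(list(nuc_partition.sample_ids), calls)

    metadata = {
        "scenario": scenario_id,
        "seed": seed,
        "params": {k: float(v) for k, v in params.items()},
        "n_mt": alignment.n,
        "n_nuclear": n_ind,
        "locus_length": model.length,
        "mu": model.mu,
        "nuclear_ne_factor": NUCLEAR_NE_FACTOR,
    }
    return StudyBundle(
        alignment, partition, genotypes, nuc_partition, design.geo_table(), metadata
    )
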