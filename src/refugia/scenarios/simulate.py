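"""Composition: parameter draw -> genealogy -> sequences -> labelled dataset."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..popgen.alignment import SequenceAlignment
from ..popgen.partition import PopulationPartition
from .coalescent import Genealogy, simulate_genealogy
from .events import DemographicScenario, build_scenario, sample_parameters
from .mutation import MutationModel, evolve_sequences
from .priors import PriorSet

#: mtDNA sample counts of the three pooled regions in the study design
DEFAULT_REGION_SIZES = {"A": 18, "C": 87, "S": 97}

REGION_NAMES = {"A": "Aleutians", "C": "Central", "S": "South"}


@dataclass
class SimulatedDataset:
    alignment: SequenceAlignment
    partition: PopulationPartition
    genealogy: Genealogy
    scenario_id: int
    params: dict[str, float]


def simulate_dataset(
    scenario: DemographicScenario | int,
    params: dict[str, float] | None = None,
    region_sizes: dict[str, int] | None = None,
    model: MutationModel | None = None,
    priors: PriorSet | None = None,
    rng: np.random.Generator | int | None = None,
) -> SimulatedDataset:
    """Simulate one mtDNA dataset under a scenario.

    When ``params`` is None a fresh prior draw is taken from ``rng``.
    Deterministic given the generator state; region labels in the returned
    partition follow the region-size design.
    """
    if isinstance(scenario, int):
        scenario = build_scenario(scenario)
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    region_sizes = dict(region_sizes or DEFAULT_REGION_SIZES)
    if any(v <= 0 for v in region_sizes.values()):
        raise ValueError("design region sizes must be positive")
    if params is None:
        params = sample_parameters(scenario, priors, rng)
    model = model or MutationModel()
    genealogy = simulate_genealogy(scenario, params, region_sizes, rng)
    alignment = evolve_sequences(genealogy, model, rng)
    regions = [REGION_NAMES[r] for r in genealogy.tip_regions]
    partition = PopulationPartition(
        list(alignment.sample_ids),
        regions[:],  # site = location = region for the pooled design
        regions[:],
        regions,
    )
    return SimulatedDataset(alignment, partition, genealogy, scenario.scenario_id, params)
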