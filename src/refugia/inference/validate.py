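"""Type I / Type II error estimation with pseudo-observed datasets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..scenarios.events import build_scenario, sample_parameters
from ..scenarios.mutation import MutationModel
from ..scenarios.priors import PriorSet
from ..scenarios.simulate import DEFAULT_REGION_SIZES, simulate_dataset
from .choice import model_choice
from .reference import ReferenceTable
from .sumstats import summary_vector


@dataclass
class ValidationReport:
    """Confusion matrix over scenarios (rows = true, cols = assigned)."""

    confusion: pd.DataFrame
    type_i: dict[int, float]  # per scenario: PODs from it not assigned to it
    type_ii: dict[int, float]  # per scenario: PODs from others assigned to it
    n_pods_per_scenario: int

    def to_frame(self) -> pd.DataFrame:
        df = self.confusion.copy()
        df["type_I"] = [self.type_i[s] for s in df.index]
        df["type_II"] = [self.type_ii[s] for s in df.index]
        return df


def validate_model_choice(
    table: ReferenceTable,
    n_pods_per_scenario: int = 50,
    n_closest: int | None = None,
    priors: PriorSet | None = None,
    region_sizes: dict[str, int] | None = None,
    model: MutationModel | None = None,
    seed: int | None = None,
) -> ValidationReport:
    """Simulate fresh PODs per scenario and score highest-posterior calls.

    POD parameters are drawn from the priors (not reused from the table).
    """
    if n_pods_per_scenario < 10:
        raise ValueError("need at least 10 PODs per scenario")
    priors = priors or PriorSet()
    model = model or MutationModel()
    region_sizes = dict(region_sizes or DEFAULT_REGION_SIZES)
    rng = np.random.default_rng(seed)
    scenarios = table.scenarios
    confusion = pd.DataFrame(0, index=scenarios, columns=scenarios)
    for true_sid in scenarios:
        scenario = build_scenario(true_sid)
        for _ in range(n_pods_per_scenario):
            params = sample_parameters(scenario, priors, rng)
            ds = simulate_dataset(scenario, params, region_sizes, model, priors, rng)
            vec = summary_vector(ds.alignment, ds.partition)
            res = model_choice(vec, table, n_closest=n_closest)
            confusion.loc[true_sid, res.best_scenario()] += 1
    type_i = {
        int(s): 1.0 - confusion.loc[s, s] / n_pods_per_scenario
        for s in scenarios
    }
    others_total = n_pods_per_scenario * (len(scenarios) - 1)
    type_ii = {
        int(s): float(
            (confusion[s].sum() - confusion.loc[s, s]) / others_total
        )
        for s in scenarios
    }
    return ValidationReport(confusion, type_i, type_ii, n_pods_per_scenario)
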