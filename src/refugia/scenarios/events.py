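"""Event-list encodings of the three refugial histories.

Populations are labelled A (Aleutians), C (Central), S (South) and ANC
(ancestral).  Events are specified backward in time by parameter name and
instantiated with a concrete parameter draw.

Scenario 1 — two refugia, Aleutians deep split:
    C merges into S at t1 (shallow); A and S merge into ANC at t2 (deep).
Scenario 2 — single southern refugium, stepwise northward colonization:
    A merges into C at ta, C merges into S at tb (ta <= tb, both shallow);
    S changes size to N_ANC at tc (deep).
Scenario 3 — two refugia with secondary contact:
    each C lineage derives from A with probability ra (else S) at t1;
    A and S merge into ANC at t2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .priors import PriorSet

POPULATIONS = ("A", "C", "S", "ANC")
SCENARIO_IDS = (1, 2, 3)

# parameter symbols per scenario (order fixed for reference-table layout)
SCENARIO_PARAMS: dict[int, tuple[str, ...]] = {
    1: ("N_A", "N_C", "N_S", "N_ANC", "t1", "t2"),
    2: ("N_A", "N_C", "N_S", "N_ANC", "ta", "tb", "tc"),
    3: ("N_A", "N_C", "N_S", "N_ANC", "t1", "t2", "ra"),
}
ALL_PARAMS: tuple[str, ...] = (
    "N_A", "N_C", "N_S", "N_ANC", "t1", "t2", "ta", "tb", "tc", "ra",
)


@dataclass(frozen=True)
class MergeSpec:
    """All lineages of ``source`` relocate to ``dest`` at the event time."""

    time_param: str
    source: str
    dest: str


@dataclass(frozen=True)
class AdmixSpec:
    """Each ``source`` lineage relocates to ``dest_a`` with probability
    ``prob_param`` (else ``dest_b``)."""

    time_param: str
    source: str
    dest_a: str
    dest_b: str
    prob_param: str


@dataclass(frozen=True)
class ResizeSpec:
    """``pop`` takes the size ``size_param`` from the event time backward."""

    time_param: str
    pop: str
    size_param: str


@dataclass(frozen=True)
class DemographicScenario:
    scenario_id: int
    events: tuple
    param_names: tuple[str, ...]

    def instantiate(self, params: dict[str, float]) -> list[tuple]:
        """Concrete (time, spec) pairs sorted by time, stable within ties."""
        missing = [p for p in self.param_names if p not in params]
        if missing:
            raise ValueError(f"missing parameters: {missing}")
        concrete = [(float(params[e.time_param]), e) for e in self.events]
        concrete.sort(key=lambda te: te[0])
        return concrete


_SCENARIOS: dict[int, DemographicScenario] = {
    1: DemographicScenario(
        1,
        (
            MergeSpec("t1", "C", "S"),
            MergeSpec("t2", "A", "ANC"),
            MergeSpec("t2", "S", "ANC"),
        ),
        SCENARIO_PARAMS[1],
    ),
    2: DemographicScenario(
        2,
        (
            MergeSpec("ta", "A", "C"),
            MergeSpec("tb", "C", "S"),
            ResizeSpec("tc", "S", "N_ANC"),
        ),
        SCENARIO_PARAMS[2],
    ),
    3: DemographicScenario(
        3,
        (
            AdmixSpec("t1", "C", "A", "S", "ra"),
            MergeSpec("t2", "A", "ANC"),
            MergeSpec("t2", "S", "ANC"),
        ),
        SCENARIO_PARAMS[3],
    ),
}


def build_scenario(scenario_id: int) -> DemographicScenario:
    try:
        return _SCENARIOS[int(scenario_id)]
    except (KeyError, ValueError) as exc:
        raise ValueError(f"unknown scenario id {scenario_id!r}") from exc


def sample_parameters(
    scenario: DemographicScenario | int,
    priors: PriorSet | None = None,
    rng: np.random.Generator | None = None,
    max_attempts: int = 1_000_000,
) -> dict[str, float]:
    """One independent uniform draw of the scenario's parameters.

    Scenario 2 redraws (ta, tb) until ta <= tb (Aleutians founded last).
    """
    if isinstance(scenario, int):
        scenario = build_scenario(scenario)
    priors = priors or PriorSet()
    rng = rng if rng is not None else np.random.default_rng()
    params: dict[str, float] = {}
    for name in scenario.param_names:
        if name.startswith("N_"):
            params[name] = float(rng.uniform(priors.ne_low, priors.ne_high))
        elif name in ("t2", "tc"):
            params[name] = float(rng.uniform(priors.deep_low, priors.deep_high))
        elif name in ("t1", "ta", "tb"):
            params[name] = float(
                rng.uniform(priors.shallow_low, priors.shallow_high)
            )
        elif name == "ra":
            params[name] = float(rng.uniform(priors.ra_low, priors.ra_high))
        else:  # pragma: no cover - guarded by SCENARIO_PARAMS
            raise ValueError(f"unknown parameter {name!r}")
    if scenario.scenario_id == 2:
        attempts = 0
        while params["ta"] > params["tb"]:
            params["ta"] = float(
                rng.uniform(priors.shallow_low, priors.shallow_high)
            )
            params["tb"] = float(
                rng.uniform(priors.shallow_low, priors.shallow_high)
            )
            attempts += 1
            if attempts > max_attempts:
                raise RuntimeError("parameter rejection loop did not terminate")
    return params


def initial_sizes(params: dict[str, float]) -> dict[str, float]:
    """Population sizes at time 0; ANC applies when the merge creates it."""
    return {
        "A": params["N_A"],
        "C": params["N_C"],
        "S": params["N_S"],
        "ANC": params["N_ANC"],
    }
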