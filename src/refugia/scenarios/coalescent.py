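"""Structured-coalescent genealogy simulation over the scenario event lists.

Within each population, pairs of lineages coalesce at rate 1/N per
generation (continuous-time approximation); merge/admix/resize events move
lineages between populations at their scheduled times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import AdmixSpec, DemographicScenario, MergeSpec, ResizeSpec, initial_sizes


@dataclass
class Genealogy:
    """Rooted binary coalescent tree with node times in generations.

    Nodes 0..n-1 are tips (time 0); internal nodes are appended in
    coalescence order, so node 2n-2 is the root.  ``node_pop`` records the
    population in which each node sits at its own time (the lineage
    trajectory of tips is implied by the event schedule).
    """

    n_tips: int
    parent: np.ndarray  # (2n-1,) int, -1 at root
    children: np.ndarray  # (n-1, 2) int, per internal node
    time: np.ndarray  # (2n-1,) float generations
    tip_ids: list[str]
    tip_regions: list[str]
    node_pop: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.n_tips
        if len(self.parent) != 2 * n - 1:
            raise ValueError("expected 2n-1 nodes")
        if (self.time[:n] != 0).any():
            raise ValueError("tips must sit at time 0")

    @property
    def root(self) -> int:
        return 2 * self.n_tips - 2

    def branch_length(self, node: int) -> float:
        p = self.parent[node]
        return float(self.time[p] - self.time[node]) if p >= 0 else 0.0

    @property
    def total_branch_length(self) -> float:
        return float(
            sum(self.branch_length(v) for v in range(2 * self.n_tips - 2))
        )

    @property
    def tmrca(self) -> float:
        return float(self.time[self.root])

    def to_newick(self) -> str:
        """Newick string with branch lengths in generations."""

        n = self.n_tips
        # iterative post-order to avoid recursion limits on caterpillars
        out: dict[int, str] = {}
        stack = [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if node < n:
                out[node] = f"{self.tip_ids[node]}:{self.branch_length(node):.6g}"
                continue
            kids = self.children[node - n]
            if not done:
                stack.append((node, True))
                stack.extend((int(k), False) for k in kids)
            else:
                inner = ",".join(out.pop(int(k)) for k in kids)
                bl = self.branch_length(node)
                label = f"({inner})"
                out[node] = (
                    f"{label};" if node == self.root else f"{label}:{bl:.6g}"
                )
        return out[self.root]


class StrandedLineagesError(RuntimeError):
    """Lineages remain in separate populations with no events left."""


def simulate_genealogy(
    scenario: DemographicScenario,
    params: dict[str, float],
    samples_per_region: dict[str, int],
    rng: np.random.Generator,
) -> Genealogy:
    """Simulate one genealogy of the sampled gene copies.

    ``samples_per_region`` maps population labels (subset of A/C/S) to tip
    counts; tips are laid out in that order.
    """
    sizes = initial_sizes(params)
    events = scenario.instantiate(params)
    tip_ids: list[str] = []
    tip_regions: list[str] = []
    active: dict[str, list[int]] = {}
    node = 0
    for pop, count in samples_per_region.items():
        if pop not in ("A", "C", "S"):
            raise ValueError(f"samples placed in non-contemporary population {pop!r}")
        if count < 0:
            raise ValueError("negative sample count")
        ids = list(range(node, node + count))
        node += count
        if count:
            active.setdefault(pop, []).extend(ids)
        tip_ids.extend(f"{pop}{i:03d}" for i in range(count))
        tip_regions.extend([pop] * count)
    n = node
    if n < 2:
        raise ValueError("need at least two sampled gene copies")

    parent = np.full(2 * n - 1, -1, dtype=int)
    children = np.zeros((n - 1, 2), dtype=int)
    time = np.zeros(2 * n - 1)
    node_pop = [""] * (2 * n - 1)
    for pop, ids in active.items():
        for i in ids:
            node_pop[i] = pop

    t = 0.0
    next_internal = n
    ev_idx = 0

    def n_lineages() -> int:
        return sum(len(v) for v in active.values())

    while n_lineages() > 1:
        rates = {
            pop: len(lin) * (len(lin) - 1) / 2.0 / sizes[pop]
            for pop, lin in active.items()
            if len(lin) >= 2
        }
        total = sum(rates.values())
        wait = rng.exponential(1.0 / total) if total > 0 else np.inf
        ev_time = events[ev_idx][0] if ev_idx < len(events) else np.inf
        if t + wait < ev_time:
            t += wait
            u = rng.random() * total
            acc = 0.0
            for pop, r in rates.items():
                acc += r
                if u <= acc:
                    break
            lin = active[pop]
            i, j = rng.choice(len(lin), size=2, replace=False)
            a, b = lin[int(i)], lin[int(j)]
            lin.remove(a)
            lin.remove(b)
            parent[a] = parent[b] = next_internal
            children[next_internal - n] = (a, b)
            time[next_internal] = t
            node_pop[next_internal] = pop
            lin.append(next_internal)
            next_internal += 1
        elif np.isinf(ev_time):
            raise StrandedLineagesError(
                f"populations {sorted(p for p, v in active.items() if v)} "
                "cannot coalesce and no events remain"
            )
        else:
            t = ev_time
            spec = events[ev_idx][1]
            ev_idx += 1
            if isinstance(spec, MergeSpec):
                moving = active.pop(spec.source, [])
                active.setdefault(spec.dest, []).extend(moving)
            elif isinstance(spec, AdmixSpec):
                moving = active.pop(spec.source, [])
                prob = float(params[spec.prob_param])
                for lid in moving:
                    dest = spec.dest_a if rng.random() < prob else spec.dest_b
                    active.setdefault(dest, []).append(lid)
            elif isinstance(spec, ResizeSpec):
                sizes[spec.pop] = float(params[spec.size_param])
            else:  # pragma: no cover
                raise TypeError(f"unknown event {spec!r}")
    return Genealogy(n, parent, children, time, tip_ids, tip_regions, node_pop)
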