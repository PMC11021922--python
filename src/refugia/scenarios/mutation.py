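"""HKY + invariant-sites + gamma sequence evolution along a genealogy.

Substitutions are placed by uniformization: the rate matrix is normalized
to one expected substitution per unit of (rate-multiplier x mu x time), a
dominating Poisson process with intensity ``lambda_max`` is thinned through
the transition kernel P = I + Q/lambda_max, and events are applied site by
site.  Per-site rate multipliers are 0 with probability I, otherwise
gamma(shape) scaled to mean 1/(1-I) so the alignment-wide mean rate is mu.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..popgen.alignment import SequenceAlignment, decode
from .coalescent import Genealogy

DEFAULT_MU = 6.5e-7  # per site per generation
DEFAULT_KAPPA = 10.0
DEFAULT_BASE_FREQS = (0.3, 0.3, 0.1, 0.3)  # A, C, G, T (control-region-like)
DEFAULT_PROP_INVARIANT = 0.796
DEFAULT_GAMMA_SHAPE = 0.733
DEFAULT_LENGTH = 723

# transition partner under A=0, C=1, G=2, T=3
_TS_PARTNER = np.array([2, 3, 0, 1])


@dataclass(frozen=True)
class MutationModel:
    mu: float = DEFAULT_MU
    kappa: float = DEFAULT_KAPPA
    base_freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS
    prop_invariant: float = DEFAULT_PROP_INVARIANT
    gamma_shape: float = DEFAULT_GAMMA_SHAPE
    length: int = DEFAULT_LENGTH

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.kappa <= 0:
            raise ValueError("kappa must be > 0")
        freqs = np.asarray(self.base_freqs, dtype=float)
        if freqs.shape != (4,) or (freqs <= 0).any() or abs(freqs.sum() - 1) > 1e-9:
            raise ValueError("base frequencies must be 4 positives summing to 1")
        if not 0 <= self.prop_invariant < 1:
            raise ValueError("prop_invariant must be in [0, 1)")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if self.length < 1:
            raise ValueError("length must be >= 1")

    def rate_matrix(self) -> np.ndarray:
        """HKY Q normalized to mean rate 1 at stationarity."""
        pi = np.asarray(self.base_freqs)
        Q = np.tile(pi, (4, 1))
        for i in range(4):
            Q[i, _TS_PARTNER[i]] *= self.kappa
        np.fill_diagonal(Q, 0.0)
        mean_rate = float(np.sum(pi[:, None] * Q))
        Q /= mean_rate
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def site_rates(self, rng: np.random.Generator) -> np.ndarray:
        """Per-site rate multipliers with overall mean 1."""
        r = np.zeros(self.length)
        variable = rng.random(self.length) >= self.prop_invariant
        nv = int(variable.sum())
        if nv:
            mean = 1.0 / (1.0 - self.prop_invariant)
            r[variable] = rng.gamma(
                self.gamma_shape, mean / self.gamma_shape, size=nv
            )
        return r


def evolve_sequences(
    genealogy: Genealogy,
    model: MutationModel | None = None,
    rng: np.random.Generator | None = None,
    site_rates: np.ndarray | None = None,
) -> SequenceAlignment:
    """Simulate sequences for the tips of a genealogy.

    The root sequence is drawn from the stationary base frequencies; each
    branch accumulates uniformized HKY events at the site-specific rates.
    """
    model = model or MutationModel()
    rng = rng if rng is not None else np.random.default_rng()
    L = model.length
    rates = model.site_rates(rng) if site_rates is None else np.asarray(site_rates)
    rate_sum = float(rates.sum())
    rate_p = rates / rate_sum if rate_sum > 0 else None

    Q = model.rate_matrix()
    lam = float(np.max(-np.diag(Q)))
    P = np.eye(4) + Q / lam
    cumP = np.cumsum(P, axis=1)
    cumP[:, -1] = 1.0  # guard rounding

    n = genealogy.n_tips
    seqs = np.empty((2 * n - 1, L), dtype=np.uint8)
    root = genealogy.root
    seqs[root] = rng.choice(4, size=L, p=np.asarray(model.base_freqs))

    # root-to-tips: internal nodes in decreasing index order have decreasing
    # coalescence times, so every parent is visited before its children
    for internal in range(root, n - 1, -1):
        for child in genealogy.children[internal - n]:
            child = int(child)
            seq = seqs[internal].copy()
            t_br = float(genealogy.time[internal] - genealogy.time[child])
            if t_br > 0 and rate_sum > 0:
                m = rng.poisson(lam * model.mu * t_br * rate_sum)
                if m:
                    sites = rng.choice(L, size=m, p=rate_p)
                    counts = np.bincount(sites, minlength=L)
                    hit = np.flatnonzero(counts)
                    remaining = counts[hit]
                    while len(hit):
                        st = seq[hit]
                        u = rng.random(len(hit))
                        seq[hit] = (u[:, None] > cumP[st, :3]).sum(axis=1)
                        remaining -= 1
                        keep = remaining > 0
                        hit, remaining = hit[keep], remaining[keep]
            seqs[child] = seq
    out = SequenceAlignment(
        list(genealogy.tip_ids), [decode(seqs[i]) for i in range(n)]
    )
    out._matrix = np.ascontiguousarray(seqs[:n])  # skip re-encoding later
    return out
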