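"""Between-sequence distances: identity and gamma-corrected Kimura 2-parameter."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import MISSING, SequenceAlignment

# transition pairs under the A<->G / C<->T encoding (A=0, C=1, G=2, T=3)
_TRANSITION = np.zeros((4, 4), dtype=bool)
for _a, _b in [(0, 2), (2, 0), (1, 3), (3, 1)]:
    _TRANSITION[_a, _b] = True


class SaturationError(ValueError):
    """Raised when observed divergence exceeds the model's resolvable range."""


@dataclass(frozen=True)
class DistanceSpec:
    """Distance model choice for AMOVA and pairwise matrices.

    model ``"identity"`` scores 1 for any non-identical pair (squared
    distance), which makes AMOVA collapse to frequency F_ST.  Model
    ``"k2p-gamma"`` applies the gamma-rate-corrected Kimura 2-parameter
    distance with shape ``alpha_dist`` (study default 0.42).
    """

    model: str = "k2p-gamma"
    alpha_dist: float = 0.42

    def __post_init__(self) -> None:
        if self.model not in ("identity", "k2p-gamma"):
            raise ValueError(f"unknown distance model {self.model!r}")
        if self.alpha_dist <= 0:
            raise ValueError("alpha_dist must be > 0")


def transition_transversion_proportions(
    a: np.ndarray, b: np.ndarray
) -> tuple[float, float]:
    """Proportions (P, Q) of transition and transversion sites.

    Sites missing in either sequence are excluded (pairwise deletion).
    """
    valid = (a != MISSING) & (b != MISSING)
    if not valid.any():
        return 0.0, 0.0
    av, bv = a[valid], b[valid]
    diff = av != bv
    ts = diff & _TRANSITION[av, bv]
    n = int(valid.sum())
    P = float(ts.sum()) / n
    Q = float((diff & ~ts).sum()) / n
    return P, Q


def k2p_gamma_from_pq(P: float, Q: float, alpha: float) -> float:
    """Gamma-K2P distance d = (a/2) [ w1^(-1/a) + w2^(-1/a)/2 - 3/2 ].

    with w1 = 1 - 2P - Q and w2 = 1 - 2Q.  Raises ``SaturationError`` when a
    power argument is non-positive (divergence beyond model range).
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"saturated pair: 1-2P-Q={w1:.4g}, 1-2Q={w2:.4g}"
        )
    inv = -1.0 / alpha
    d = (alpha / 2.0) * (w1**inv + 0.5 * w2**inv - 1.5)
    # exact-identity pairs can land at -0.0 through rounding
    return max(float(d), 0.0)


def k2p_gamma(seq_a, seq_b, spec: DistanceSpec | None = None) -> float:
    """Gamma-corrected K2P distance between two aligned sequences.

    Accepts strings or encoded uint8 rows of equal length.
    """
    from .alignment import encode

    spec = spec or DistanceSpec()
    a = encode(seq_a) if isinstance(seq_a, str) else np.asarray(seq_a)
    b = encode(seq_b) if isinstance(seq_b, str) else np.asarray(seq_b)
    if a.shape != b.shape:
        raise ValueError("sequences have unequal lengths")
    P, Q = transition_transversion_proportions(a, b)
    return k2p_gamma_from_pq(P, Q, spec.alpha_dist)


def distance_matrix(alignment: SequenceAlignment, spec: DistanceSpec) -> np.ndarray:
    """Symmetric matrix of squared distances for AMOVA.

    identity: 1 for distinct haplotypes (over globally complete sites).
    k2p-gamma: the corrected distance itself is used as the squared
    distance, matching the usual AMOVA convention for model distances.
    """
    n = alignment.n
    mat = alignment.matrix
    out = np.zeros((n, n))
    if spec.model == "identity":
        from .alignment import haplotype_assignments

        hap = haplotype_assignments(alignment)
        out = (hap[:, None] != hap[None, :]).astype(float)
        return out
    # K2P-gamma with pairwise deletion, vectorized over site axis per pair
    valid = mat != MISSING
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nv = int(both.sum())
            if nv == 0:
                d = 0.0
            else:
                ai, bj = mat[i][both], mat[j][both]
                diff = ai != bj
                ts = diff & _TRANSITION[ai, bj]
                P = float(ts.sum()) / nv
                Q = float(diff.sum() - ts.sum()) / nv
                d = k2p_gamma_from_pq(P, Q, spec.alpha_dist)
            out[i, j] = out[j, i] = d
    return out
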