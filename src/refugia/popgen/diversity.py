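"""Diversity and frequency-spectrum statistics on alignments.

All per-site statistics use complete-deletion: sites with any missing or
ambiguous base are excluded globally before counting.
"""

from __future__ import annotations

import numpy as np

from .alignment import MISSING, HaplotypeTable, SequenceAlignment


def haplotype_diversity(table: HaplotypeTable) -> float:
    """Unbiased gene (haplotype) diversity h = n/(n-1) * (1 - sum p_i^2)."""
    n = table.n
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = table.frequencies
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def pairwise_difference_matrix(matrix: np.ndarray) -> np.ndarray:
    """(n, n) counts of differing sites between all row pairs.

    Missing entries (code MISSING) are excluded per pair.  Computed with
    one-hot matrix products, so it is BLAS-bound rather than a Python loop.
    """
    n = matrix.shape[0]
    valid = (matrix != MISSING).astype(np.float64)
    shared = valid @ valid.T  # sites defined in both rows
    same = np.zeros((n, n), dtype=np.float64)
    for base in range(4):
        m = (matrix == base).astype(np.float64)
        same += m @ m.T
    diff = shared - same
    np.fill_diagonal(diff, 0.0)
    return diff


def pairwise_diff_stats(alignment: SequenceAlignment) -> tuple[float, float]:
    """Mean and (population) variance of pairwise difference counts.

    Differences are counted on globally complete sites, so ``mean / L_valid``
    equals nucleotide diversity.
    """
    if alignment.n < 2:
        raise ValueError("need at least two sequences")
    mat = alignment.valid_columns()
    d = pairwise_difference_matrix(mat)
    iu = np.triu_indices(alignment.n, k=1)
    vals = d[iu]
    return float(vals.mean()), float(vals.var())


def nucleotide_diversity(alignment: SequenceAlignment) -> float:
    """Per-site nucleotide diversity: mean pairwise differences / valid length."""
    if alignment.n < 2:
        raise ValueError("need at least two sequences")
    n_valid = int((~alignment.missing_mask).sum())
    if n_valid == 0:
        return 0.0
    mean, _ = pairwise_diff_stats(alignment)
    return mean / n_valid


def segregating_sites(matrix: np.ndarray) -> np.ndarray:
    """Boolean mask of polymorphic columns, ignoring missing entries."""
    L = matrix.shape[1]
    # a column is segregating if >= 2 distinct non-missing bases occur
    present = np.zeros((4, L), dtype=bool)
    for base in range(4):
        present[base] = (matrix == base).any(axis=0)
    return present.sum(axis=0) >= 2


def num_segregating_sites(alignment: SequenceAlignment) -> int:
    return int(segregating_sites(alignment.valid_columns()).sum())


def _tajima_constants(n: int) -> dict[str, float]:
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(alignment: SequenceAlignment) -> float:
    """Tajima's D from S and the mean pairwise difference.

    Returns NaN when there are no segregating sites (D is undefined);
    downstream consumers replace the sentinel explicitly.
    """
    n = alignment.n
    if n < 2:
        raise ValueError("need at least two sequences")
    S = num_segregating_sites(alignment)
    if S == 0:
        return float("nan")
    c = _tajima_constants(n)
    mean_pi, _ = pairwise_diff_stats(alignment)
    theta_w = S / c["a1"]
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((mean_pi - theta_w) / np.sqrt(var))
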