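"""Analysis of molecular variance: Phi_ST on sequence distances, F_ST on
allele identity, with label-permutation significance tests.

One hierarchical level is analysed at a time (among groups / within groups).
The matrix entries are treated as squared distances; with the identity model
the statistic collapses to frequency-based F_ST.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import SequenceAlignment
from .distance import DistanceSpec, distance_matrix
from .genotypes import GenotypeTable
from .partition import PopulationPartition


@dataclass
class AmovaResult:
    statistic_name: str  # "Phi_ST" or "F_ST"
    statistic: float  # unclamped
    sigma_among: float
    sigma_within: float
    p_value: float | None
    n_perm: int
    pairwise: pd.DataFrame | None = field(default=None, repr=False)
    pairwise_p: pd.DataFrame | None = field(default=None, repr=False)


def _check_square(d2: np.ndarray) -> np.ndarray:
    d2 = np.asarray(d2, dtype=float)
    if d2.ndim != 2 or d2.shape[0] != d2.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d2, d2.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d2), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    return d2


def variance_components(
    d2: np.ndarray, groups: list[np.ndarray]
) -> tuple[float, float, float]:
    """(statistic, sigma_among, sigma_within) from squared distances.

    Standard one-level AMOVA: SS_total = sum d2 / (2N); SS_within pools
    (1/(2 n_g)) sums within groups; the among-group component uses the
    average group size correction n' = (N - sum n_g^2 / N)/(G-1).
    """
    N = d2.shape[0]
    G = len(groups)
    if G < 2:
        raise ValueError("AMOVA needs at least two groups")
    sizes = np.array([len(g) for g in groups], dtype=float)
    if (sizes < 1).any():
        raise ValueError("every group needs at least one sample")
    ss_total = d2.sum() / (2.0 * N)
    ss_within = 0.0
    for g in groups:
        ss_within += d2[np.ix_(g, g)].sum() / (2.0 * len(g))
    ss_among = ss_total - ss_within
    df_among = G - 1
    df_within = N - G
    if df_within <= 0:
        raise ValueError("need more samples than groups")
    sigma_w = ss_within / df_within
    n_prime = (N - float(np.sum(sizes**2)) / N) / df_among
    sigma_a = (ss_among / df_among - sigma_w) / n_prime
    denom = sigma_a + sigma_w
    stat = sigma_a / denom if denom != 0 else 0.0
    return float(stat), float(sigma_a), float(sigma_w)


def _perm_pvalue(
    d2: np.ndarray,
    sizes: list[int],
    observed: float,
    n_perm: int,
    rng: np.random.Generator,
) -> float:
    """p = (b+1)/(B+1) where b counts permuted statistics >= observed."""
    N = d2.shape[0]
    bounds = np.cumsum([0] + sizes)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(N)
        groups = [perm[bounds[i] : bounds[i + 1]] for i in range(len(sizes))]
        stat, _, _ = variance_components(d2, groups)
        if stat >= observed - 1e-12:
            b += 1
    return (b + 1) / (n_perm + 1)


def amova(
    data: SequenceAlignment | np.ndarray,
    partition: PopulationPartition,
    spec: DistanceSpec | None = None,
    level: str = "location",
    n_perm: int = 10_000,
    seed: int | None = None,
    pairwise: bool = True,
) -> AmovaResult:
    """Global and pairwise Phi_ST (or F_ST under identity distances).

    ``data`` is an alignment (distances built per ``spec``) or a
    precomputed squared-distance matrix.  Pairwise tests use permutations
    restricted to the pair's samples.
    """
    spec = spec or DistanceSpec()
    if isinstance(data, SequenceAlignment):
        if data.n != partition.n:
            raise ValueError("alignment and partition sample counts differ")
        d2 = distance_matrix(data, spec)
    else:
        d2 = _check_square(data)
        if d2.shape[0] != partition.n:
            raise ValueError("matrix and partition sample counts differ")
    grp = partition.group_indices(level)
    if len(grp) < 2:
        raise ValueError("AMOVA needs at least two groups")
    names = list(grp)
    groups = [grp[g] for g in names]
    stat, sa, sw = variance_components(d2, groups)
    stat_name = "F_ST" if spec.model == "identity" else "Phi_ST"
    rng = np.random.default_rng(seed)
    p = None
    if n_perm > 0:
        p = _perm_pvalue(d2, [len(g) for g in groups], stat, n_perm, rng)
    pw_est = pw_p = None
    if pairwise and len(names) > 2:
        pw_est = pd.DataFrame(np.nan, index=names, columns=names)
        pw_p = pd.DataFrame(np.nan, index=names, columns=names)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                idx = np.concatenate([groups[i], groups[j]])
                sub = d2[np.ix_(idx, idx)]
                gi = np.arange(len(groups[i]))
                gj = np.arange(len(groups[i]), len(idx))
                s, _, _ = variance_components(sub, [gi, gj])
                pw_est.iloc[i, j] = pw_est.iloc[j, i] = s
                if n_perm > 0:
                    pp = _perm_pvalue(
                        sub, [len(gi), len(gj)], s, n_perm, rng
                    )
                    pw_p.iloc[i, j] = pw_p.iloc[j, i] = pp
    return AmovaResult(stat_name, stat, sa, sw, p, n_perm, pw_est, pw_p)


# ---------------------------------------------------------------------------
# diploid multilocus F_ST from allele counts

def _locus_components(
    codes: np.ndarray, n_alleles: int, group_of: np.ndarray, n_groups: int
) -> tuple[float, float] | None:
    """(sigma_among, sigma_within) for one locus from gene-copy counts.

    Works on the count identity sum_{i,j in g} 1[a_i != a_j] =
    n_g^2 - sum_k c_gk^2, i.e. allele-count sums of squares.  Returns None
    for loci that are monomorphic or observed in < 2 groups.
    """
    if n_alleles < 2:
        return None
    # expand to gene copies
    copy_group = np.repeat(group_of, 2)
    copy_allele = codes.ravel()
    ok = copy_allele >= 0
    copy_group, copy_allele = copy_group[ok], copy_allele[ok]
    gsizes = np.bincount(copy_group, minlength=n_groups).astype(float)
    present = gsizes > 0
    if present.sum() < 2:
        return None
    counts = np.zeros((n_groups, n_alleles))
    np.add.at(counts, (copy_group, copy_allele), 1.0)
    N = float(gsizes.sum())
    G = int(present.sum())
    total_counts = counts.sum(axis=0)
    ss_total = (N - float(np.sum(total_counts**2)) / N) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        per_group = (gsizes - np.einsum("ga,ga->g", counts, counts) / gsizes) / 2.0
    ss_within = float(np.nansum(per_group[present]))
    ss_among = ss_total - ss_within
    df_among = G - 1
    df_within = N - G
    if df_within <= 0:
        return None
    sigma_w = ss_within / df_within
    n_prime = (N - float(np.sum(gsizes[present] ** 2)) / N) / df_among
    sigma_a = (ss_among / df_among - sigma_w) / n_prime
    return float(sigma_a), float(sigma_w)


def _multilocus_fst(
    loci: list[tuple[np.ndarray, int]], group_of: np.ndarray, n_groups: int
) -> tuple[float, float, float] | None:
    sa = sw = 0.0
    any_poly = False
    for codes, n_alleles in loci:
        comp = _locus_components(codes, n_alleles, group_of, n_groups)
        if comp is None:
            continue
        any_poly = True
        sa += comp[0]
        sw += comp[1]
    if not any_poly:
        return None
    denom = sa + sw
    return (sa / denom if denom != 0 else 0.0, sa, sw)


def diploid_fst(
    genotypes: GenotypeTable,
    partition: PopulationPartition,
    level: str = "location",
    n_perm: int = 10_000,
    seed: int | None = None,
    pairwise: bool = True,
) -> AmovaResult:
    """Multilocus AMOVA F_ST on diploid data (identity distance).

    Variance components are summed across loci before forming the ratio;
    the permutation test shuffles individuals (both alleles together)
    among groups, jointly across loci.
    """
    if genotypes.n != partition.n:
        raise ValueError("genotype table and partition sample counts differ")
    grp = partition.group_indices(level)
    if len(grp) < 2:
        raise ValueError("F_ST needs at least two groups")
    names = list(grp)
    group_of = np.empty(partition.n, dtype=int)
    for gi, name in enumerate(names):
        group_of[grp[name]] = gi
    loci = [genotypes.locus_codes(l) for l in genotypes.loci]
    res = _multilocus_fst(loci, group_of, len(names))
    if res is None:
        raise ValueError("all loci monomorphic")
    obs, sa_obs, sw_obs = res
    rng = np.random.default_rng(seed)
    p = None
    if n_perm > 0:
        b = 0
        for _ in range(n_perm):
            perm_groups = group_of[rng.permutation(partition.n)]
            s = _multilocus_fst(loci, perm_groups, len(names))
            if s is not None and s[0] >= obs - 1e-12:
                b += 1
        p = (b + 1) / (n_perm + 1)
    pw_est = pw_p = None
    if pairwise and len(names) > 2:
        pw_est = pd.DataFrame(np.nan, index=names, columns=names)
        pw_p = pd.DataFrame(np.nan, index=names, columns=names)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                idx = np.concatenate([grp[names[i]], grp[names[j]]])
                sub_loci = [(codes[idx], na) for codes, na in loci]
                sub_groups = np.array(
                    [0] * len(grp[names[i]]) + [1] * len(grp[names[j]])
                )
                s = _multilocus_fst(sub_loci, sub_groups, 2)
                if s is None:
                    continue
                pw_est.iloc[i, j] = pw_est.iloc[j, i] = s[0]
                if n_perm > 0:
                    b = 0
                    for _ in range(n_perm):
                        pg = sub_groups[rng.permutation(len(idx))]
                        sp = _multilocus_fst(sub_loci, pg, 2)
                        if sp is not None and sp[0] >= s[0] - 1e-12:
                            b += 1
                    pw_p.iloc[i, j] = pw_p.iloc[j, i] = (b + 1) / (n_perm + 1)
    return AmovaResult("F_ST", obs, sa_obs, sw_obs, p, n_perm, pw_est, pw_p)
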