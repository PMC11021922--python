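"""The 39-value summary-statistic vector used for scenario choice.

Eight single-sample statistics per region (Aleutians, Central, South) plus
five two-sample statistics per region pair, in a fixed documented order.
An undefined Tajima's D (no segregating sites) is stored as 0 with a
companion flag so the sentinel can be excluded from distance computations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..popgen.alignment import SequenceAlignment
from ..popgen.diversity import _tajima_constants
from ..popgen.partition import REGIONS, PopulationPartition

SINGLE_STATS = (
    "k",
    "S",
    "mean_pairwise_diff",
    "var_pairwise_diff",
    "tajima_d",
    "private_S",
    "rarest_count_mean",
    "rarest_count_var",
)
PAIR_STATS = (
    "pooled_k",
    "pooled_S",
    "mean_within_diff",
    "mean_between_diff",
    "hudson_fst",
)
REGION_KEYS = ("A", "C", "S")
PAIR_KEYS = (("A", "C"), ("A", "S"), ("C", "S"))


def stat_names() -> list[str]:
    names = [f"{r}_{s}" for r in REGION_KEYS for s in SINGLE_STATS]
    names += [f"{a}{b}_{s}" for a, b in PAIR_KEYS for s in PAIR_STATS]
    return names


def flag_names() -> list[str]:
    return [f"{r}_tajima_undef" for r in REGION_KEYS]


N_STATS = 39


@dataclass
class SummaryStatVector:
    values: np.ndarray  # (39,)
    d_undefined: np.ndarray  # (3,) bool, per region

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.d_undefined = np.asarray(self.d_undefined, dtype=bool)
        if self.values.shape != (N_STATS,):
            raise ValueError(f"expected {N_STATS} statistics")
        if self.d_undefined.shape != (3,):
            raise ValueError("expected 3 Tajima-undefined flags")

    @property
    def names(self) -> list[str]:
        return stat_names()


def _base_counts(mat: np.ndarray) -> np.ndarray:
    """(4, L) counts of each base per column."""
    return np.stack([(mat == b).sum(axis=0) for b in range(4)])


def _diff_matrix(mat: np.ndarray) -> np.ndarray:
    """Pairwise difference counts via one-hot products (no missing data)."""
    L = mat.shape[1]
    same = np.zeros((mat.shape[0], mat.shape[0]), dtype=np.float32)
    for b in range(4):
        m = (mat == b).astype(np.float32)
        same += m @ m.T
    return L - same


def _pair_mean(d: np.ndarray, rows: np.ndarray, cols: np.ndarray | None = None):
    if cols is None:
        sub = d[np.ix_(rows, rows)]
        m = len(rows)
        if m < 2:
            return 0.0, 0.0
        iu = np.triu_indices(m, k=1)
        vals = sub[iu]
        return float(vals.mean()), float(vals.var())
    vals = d[np.ix_(rows, cols)].ravel()
    return float(vals.mean()), float(vals.var())


def _unique_rows(mat: np.ndarray) -> int:
    if mat.shape[1] == 0:
        return 1
    # hashing row bytes beats np.unique(axis=0) by an order of magnitude here
    return len({row.tobytes() for row in np.ascontiguousarray(mat)})


def summary_vector(
    alignment: SequenceAlignment, partition: PopulationPartition
) -> SummaryStatVector:
    """Compute the 39 statistics for a 3-region dataset.

    Regions must be named Aleutians/Central/South and each hold >= 2
    samples; statistics use globally complete sites.
    """
    if alignment.n != partition.n:
        raise ValueError("alignment and partition sample counts differ")
    groups = partition.group_indices("region")
    missing = [r for r in REGIONS if r not in groups]
    if missing:
        raise ValueError(f"missing regions: {missing}")
    idx = {key: groups[name] for key, name in zip(REGION_KEYS, REGIONS)}
    for key, rows in idx.items():
        if len(rows) < 2:
            raise ValueError(f"region {key} has fewer than 2 samples")
    mat = alignment.valid_columns()
    diffs = _diff_matrix(mat)

    counts = {key: _base_counts(mat[rows]) for key, rows in idx.items()}
    present = {key: counts[key] > 0 for key in idx}
    seg = {key: present[key].sum(axis=0) >= 2 for key in idx}

    values: list[float] = []
    flags = np.zeros(3, dtype=bool)
    for ri, key in enumerate(REGION_KEYS):
        rows = idx[key]
        n = len(rows)
        sub = mat[rows]
        k = _unique_rows(sub)
        S = int(seg[key].sum())
        mean_pw, var_pw = _pair_mean(diffs, rows)
        c = _tajima_constants(n) if S else None
        var = c["e1"] * S + c["e2"] * S * (S - 1) if S else 0.0
        if S == 0 or var <= 0:  # undefined (no variation, or n = 2)
            d_taj = 0.0
            flags[ri] = True
        else:
            d_taj = float((mean_pw - S / c["a1"]) / np.sqrt(var))
        other_keys = [o for o in REGION_KEYS if o != key]
        other_present = present[other_keys[0]] | present[other_keys[1]]
        others_mono = other_present.sum(axis=0) <= 1
        private_S = int((seg[key] & others_mono).sum())
        if S > 0:
            seg_counts = counts[key][:, seg[key]].astype(float)
            seg_counts[seg_counts == 0] = np.inf  # absent bases can't be rarest
            rarest = seg_counts.min(axis=0)
            rarest_mean = float(rarest.mean())
            rarest_var = float(rarest.var())
        else:
            rarest_mean = rarest_var = 0.0
        values += [k, S, mean_pw, var_pw, d_taj, private_S, rarest_mean, rarest_var]

    for a, b in PAIR_KEYS:
        rows_a, rows_b = idx[a], idx[b]
        pooled = np.concatenate([rows_a, rows_b])
        pooled_k = _unique_rows(mat[pooled])
        pooled_S = int(((present[a] | present[b]).sum(axis=0) >= 2).sum())
        wa, _ = _pair_mean(diffs, rows_a)
        wb, _ = _pair_mean(diffs, rows_b)
        mean_within = 0.5 * (wa + wb)
        mean_between, _ = _pair_mean(diffs, rows_a, rows_b)
        if mean_between > 0:
            fst = 1.0 - mean_within / mean_between
        else:
            fst = 0.0
        values += [pooled_k, pooled_S, mean_within, mean_between, fst]

    return SummaryStatVector(np.asarray(values), flags)
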