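"""Aligned haploid sequences and haplotype collapsing.

The alignment is the unit of all mitochondrial computation.  Sequences are
stored as strings but encoded on demand into a small integer matrix
(A,C,G,T -> 0..3, anything else -> MISSING) that the numeric routines share.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MISSING = 255

_CODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_DECODE = np.full(256, ord("N"), dtype=np.uint8)
_DECODE[:4] = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string into uint8 codes (non-ACGT -> MISSING)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(row: np.ndarray) -> str:
    """Decode uint8 codes back to an ACGT/N string."""
    return _DECODE[row].tobytes().decode("ascii")


@dataclass
class SequenceAlignment:
    """Equal-length haploid sequences with unique sample ids.

    Parameters
    ----------
    sample_ids:
        Unique identifiers, one per sequence.
    sequences:
        Equal-length strings over ``{A, C, G, T, N, -}`` (IUPAC ambiguity
        codes are tolerated and treated as missing).
    """

    sample_ids: list[str]
    sequences: list[str]
    _matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.sequences):
            raise ValueError("sample_ids and sequences differ in length")
        if len(self.sequences) == 0:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        if self.length < 1:
            raise ValueError("alignment length must be >= 1")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def matrix(self) -> np.ndarray:
        """(n, L) uint8 code matrix; cached after first use."""
        if self._matrix is None:
            self._matrix = np.vstack([encode(s) for s in self.sequences])
        return self._matrix

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (L,) mask of sites with any missing/ambiguous base."""
        return (self.matrix == MISSING).any(axis=0)

    def valid_columns(self) -> np.ndarray:
        """Matrix restricted to globally complete sites."""
        return self.matrix[:, ~self.missing_mask]

    def subset(self, indices) -> "SequenceAlignment":
        indices = list(indices)
        return SequenceAlignment(
            [self.sample_ids[i] for i in indices],
            [self.sequences[i] for i in indices],
        )

    def take(self, ids: list[str]) -> "SequenceAlignment":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return self.subset([pos[s] for s in ids])


@dataclass
class HaplotypeTable:
    """Distinct sequences with their multiplicities."""

    haplotype_seqs: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts <= 0).any():
            raise ValueError("haplotype counts must be positive")
        if len(self.haplotype_seqs) != len(self.counts):
            raise ValueError("sequences/counts length mismatch")

    @property
    def k(self) -> int:
        return len(self.counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n


def collapse_haplotypes(alignment: SequenceAlignment) -> HaplotypeTable:
    """Group sequences identical at all unmasked (globally complete) sites.

    Sites carrying a missing or ambiguous base in any sequence are excluded
    from the comparison; the representative sequence stored for each
    haplotype is the first full-length member encountered.
    """
    mat = alignment.valid_columns()
    if mat.shape[1] == 0:
        # everything masked: a single haplotype class
        mat = np.zeros((alignment.n, 1), dtype=np.uint8)
    _, first_idx, inverse = np.unique(
        mat, axis=0, return_index=True, return_inverse=True
    )
    order = np.argsort(first_idx)  # preserve first-appearance order
    rank = np.empty_like(order)
    rank[order] = np.arange(len(order))
    counts = np.bincount(rank[inverse])
    seqs = [alignment.sequences[first_idx[i]] for i in order]
    return HaplotypeTable(seqs, counts)


def haplotype_assignments(alignment: SequenceAlignment) -> np.ndarray:
    """Integer haplotype label per sample (same grouping as collapse)."""
    mat = alignment.valid_columns()
    if mat.shape[1] == 0:
        return np.zeros(alignment.n, dtype=int)
    _, inverse = np.unique(mat, axis=0, return_inverse=True)
    return inverse
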