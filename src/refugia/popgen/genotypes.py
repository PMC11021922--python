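"""Diploid genotype tables for nuclear loci."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING_ALLELE = "."


@dataclass
class GenotypeTable:
    """Two alleles per sample per locus; missing genotypes as ``"."``.

    ``calls`` maps locus name -> (n_samples, 2) object array of allele ids
    (microsatellite alleles are repeat lengths rendered as strings).
    """

    sample_ids: list[str]
    calls: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.calls)) != len(self.calls):
            raise ValueError("duplicate locus names")
        n = len(self.sample_ids)
        for locus, arr in self.calls.items():
            arr = np.asarray(arr, dtype=object)
            if arr.shape != (n, 2):
                raise ValueError(f"locus {locus!r}: expected shape {(n, 2)}")
            half = (arr == MISSING_ALLELE).sum(axis=1)
            if np.any((half != 0) & (half != 2)):
                raise ValueError(f"locus {locus!r}: half-missing genotype")
            self.calls[locus] = arr

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def loci(self) -> list[str]:
        return list(self.calls)

    def locus_codes(self, locus: str) -> tuple[np.ndarray, int]:
        """Integer-coded alleles for one locus: (n, 2) int array, n_alleles.

        Missing alleles are coded -1.
        """
        arr = self.calls[locus]
        flat = arr.ravel()
        present = flat != MISSING_ALLELE
        codes = np.full(flat.shape, -1, dtype=int)
        if present.any():
            uniq, inv = np.unique(flat[present].astype(str), return_inverse=True)
            codes[present] = inv
            n_alleles = len(uniq)
        else:
            n_alleles = 0
        return codes.reshape(arr.shape), n_alleles

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for locus, arr in self.calls.items():
            for sid, (a1, a2) in zip(self.sample_ids, arr):
                rows.append((sid, locus, a1, a2))
        return pd.DataFrame(rows, columns=["sample_id", "locus", "allele1", "allele2"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        required = {"sample_id", "locus", "allele1", "allele2"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"genotype table missing columns: {sorted(missing)}")
        sample_ids = list(dict.fromkeys(df["sample_id"].astype(str)))
        pos = {s: i for i, s in enumerate(sample_ids)}
        calls: dict[str, np.ndarray] = {}
        for locus, sub in df.groupby("locus", sort=False):
            arr = np.full((len(sample_ids), 2), MISSING_ALLELE, dtype=object)
            for _, row in sub.iterrows():
                i = pos[str(row["sample_id"])]
                arr[i, 0] = str(row["allele1"])
                arr[i, 1] = str(row["allele2"])
            calls[str(locus)] = arr
        return cls(sample_ids, calls)
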