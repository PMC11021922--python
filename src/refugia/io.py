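"""Readers and writers for the plain-text interchange formats.

FASTA via Biopython; popmap / coords / genotype tables as TSV.  Result
tables are written with a single ``#``-prefixed metadata header line so that
runs are traceable to a seed and config.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .popgen.alignment import SequenceAlignment
from .popgen.genotypes import GenotypeTable
from .popgen.ibd import GeoTable
from .popgen.partition import PopulationPartition


def read_fasta(path) -> SequenceAlignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return SequenceAlignment(
        [r.id for r in records], [str(r.seq).upper() for r in records]
    )


def write_fasta(alignment: SequenceAlignment, path) -> None:
    records = [
        SeqRecord(Seq(s), id=sid, description="")
        for sid, s in zip(alignment.sample_ids, alignment.sequences)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")  # wraps at 60/80 per Biopython


def read_popmap(path) -> PopulationPartition:
    return PopulationPartition.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_popmap(partition: PopulationPartition, path) -> None:
    partition.to_frame().to_csv(path, sep="\t", index=False)


def read_coords(path) -> GeoTable:
    return GeoTable.from_frame(pd.read_csv(path, sep="\t"))


def write_coords(geo: GeoTable, path) -> None:
    geo.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path) -> GenotypeTable:
    return GenotypeTable.from_frame(pd.read_csv(path, sep="\t", dtype=str))


def write_genotypes(genotypes: GenotypeTable, path) -> None:
    genotypes.to_frame().to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    """TSV with an optional leading '# key=value ...' metadata line."""
    path = Path(path)
    buf = _io.StringIO()
    if metadata:
        items = " ".join(f"{k}={v}" for k, v in metadata.items())
        buf.write(f"# {items}\n")
    df.to_csv(buf, sep="\t")
    path.write_text(buf.getvalue())


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
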