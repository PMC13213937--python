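"""Reading and writing of the standard formats used across the toolkit.

FASTA and FASTQ go through Biopython; GFF3 is handled as the 9-column
tab-separated table it is, with a plain ``key=value`` attribute field.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GFF3_COLUMNS = [
    "seq_id",
    "source",
    "type",
    "start",
    "end",
    "score",
    "strand",
    "phase",
    "attributes",
]


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA file as an ordered ``{id: sequence}`` mapping (upper-cased)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)


@dataclass
class FastqRead:
    read_id: str
    sequence: str


def read_fastq(path: str | os.PathLike) -> list[FastqRead]:
    return [
        FastqRead(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(reads: Iterable[FastqRead], path: str | os.PathLike) -> None:
    """Write reads with a fixed quality of 'I' (Phred 40)."""
    with open(path, "w") as fh:
        for read in reads:
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{'I' * len(read.sequence)}\n")


@dataclass
class Gff3Feature:
    """One GFF3 feature line; start/end stored 0-based half-open internally."""

    seq_id: str
    type: str
    start: int
    end: int
    strand: str
    attributes: dict[str, str] = field(default_factory=dict)

    @property
    def feature_id(self) -> str | None:
        return self.attributes.get("ID")

    @property
    def parent(self) -> str | None:
        return self.attributes.get("Parent")


def _parse_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff3(path: str | os.PathLike) -> list[Gff3Feature]:
    table = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=GFF3_COLUMNS,
        dtype={"seq_id": str, "attributes": str},
    )
    return [
        Gff3Feature(
            seq_id=row.seq_id,
            type=row.type,
            start=int(row.start) - 1,
            end=int(row.end),
            strand=row.strand,
            attributes=_parse_attributes(row.attributes),
        )
        for row in table.itertuples()
    ]


def write_gff3(features: Iterable[Gff3Feature], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = ";".join(f"{k}={v}" for k, v in f.attributes.items())
            fh.write(
                f"{f.seq_id}\t.\t{f.type}\t{f.start + 1}\t{f.end}\t.\t{f.strand}\t.\t{attrs}\n"
            )


def write_tsv(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
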