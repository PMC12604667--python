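"""Light wrappers around gzipped FASTQ/FASTA input and output.

Reading goes through :class:`pysam.FastxFile`, which transparently handles
gzip compression; writing is plain text through :mod:`gzip` so that outputs
stay byte-reproducible.
"""

from __future__ import annotations

import gzip
import os
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional

import pysam


@dataclass(frozen=True)
class FastqRecord:
    name: str
    sequence: str
    quality: str
    comment: Optional[str] = None

    def to_string(self) -> str:
        header = f"@{self.name}"
        if self.comment:
            header += f" {self.comment}"
        return f"{header}\n{self.sequence}\n+\n{self.quality}\n"


def read_fastq(path: str | os.PathLike) -> Iterator[FastqRecord]:
    """Yield records from a (optionally gzipped) FASTQ file."""
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            if rec.quality is None:
                raise ValueError(f"{path}: record {rec.name} has no quality line")
            yield FastqRecord(rec.name, rec.sequence, rec.quality, rec.comment)


def read_fastq_pairs(
    r1_path: str | os.PathLike, r2_path: str | os.PathLike
) -> Iterator[tuple[FastqRecord, FastqRecord]]:
    """Yield synchronized (R1, R2) record pairs.

    Raises ``ValueError`` naming the record index if one file is truncated
    relative to the other.
    """
    it1 = read_fastq(r1_path)
    it2 = read_fastq(r2_path)
    idx = 0
    while True:
        rec1 = next(it1, None)
        rec2 = next(it2, None)
        if rec1 is None and rec2 is None:
            return
        if rec1 is None or rec2 is None:
            which = r1_path if rec1 is None else r2_path
            raise ValueError(
                f"FASTQ pair length mismatch: {which} truncated at record {idx}"
            )
        yield rec1, rec2
        idx += 1


class FastqWriter:
    """Append-style FASTQ writer; gzip-compressed when the path ends in .gz."""

    def __init__(self, path: str | os.PathLike):
        self.path = str(path)
        if self.path.endswith(".gz"):
            self._fh = gzip.open(self.path, "wt")
        else:
            self._fh = open(self.path, "wt")

    def write(self, record: FastqRecord) -> None:
        self._fh.write(record.to_string())

    def close(self) -> None:
        self._fh.close()

    def __enter__(self) -> "FastqWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def write_fastq(path: str | os.PathLike, records: Iterable[FastqRecord]) -> int:
    n = 0
    with FastqWriter(path) as out:
        for rec in records:
            out.write(rec)
            n += 1
    return n


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    """Return (header, sequence) tuples; header is the full description line."""
    from Bio import SeqIO

    out = []
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            out.append((rec.description, str(rec.seq).upper()))
    return out


def write_fasta(path: str | os.PathLike, records: Iterable[tuple[str, str]]) -> int:
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
            n += 1
    return n
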