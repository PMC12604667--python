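"""Sample-tag demultiplexing of multiplexed single-cell runs.

Multiplexed libraries label each donor's cells with a short sample-tag
oligo.  Counting tag evidence per cell barcode gives a barcodes x tags
matrix; a barcode is assigned to a donor when a single tag accounts for at
least 75% of its tag reads (the dominant-tag rule), classified as a
multiplet when no tag does, and left undetermined when it has no tag reads
at all.  Assigned barcodes drive the splitting of the original FASTQ pair
into per-donor FASTQ pairs; reads from multiplet/undetermined barcodes are
dropped.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

from ._fastq import FastqRecord, FastqWriter, read_fastq_pairs

log = logging.getLogger(__name__)

STATUS_ASSIGNED = "assigned"
STATUS_MULTIPLET = "multiplet"
STATUS_UNDETERMINED = "undetermined"


@dataclass(frozen=True)
class BarcodeSpec:
    """0-based half-open coordinates of barcode and UMI within R1."""

    bc_start: int = 0
    bc_len: int = 16
    umi_start: int = 16
    umi_len: int = 12

    def barcode(self, r1_seq: str) -> str:
        return r1_seq[self.bc_start : self.bc_start + self.bc_len]

    def umi(self, r1_seq: str) -> str:
        return r1_seq[self.umi_start : self.umi_start + self.umi_len]


@dataclass
class TagCountMatrix:
    barcodes: list[str]
    tags: list[str]
    counts: np.ndarray  # (n_barcodes, n_tags) int

    def __post_init__(self) -> None:
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcodes must be unique")
        if len(set(self.tags)) != len(self.tags):
            raise ValueError("tags must be unique")
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if (self.counts < 0).any():
            raise ValueError("tag counts must be non-negative")
        if self.counts.shape != (len(self.barcodes), len(self.tags)):
            raise ValueError("count matrix shape mismatch")


def _matches(window: str, tag: str, tol: int) -> bool:
    if len(window) != len(tag):
        return False
    if tol == 0:
        return window == tag
    mism = 0
    for a, b in zip(window, tag):
        if a != b:
            mism += 1
            if mism > tol:
                return False
    return True


def _find_tag(
    r2_seq: str, tags: list[tuple[str, str]], tol: int, offset: Optional[int]
) -> Optional[str]:
    for tag_id, tag_seq in tags:
        if offset is not None:
            if _matches(r2_seq[offset : offset + len(tag_seq)], tag_seq, tol):
                return tag_id
        elif tol == 0:
            if tag_seq in r2_seq:
                return tag_id
        else:
            for off in range(len(r2_seq) - len(tag_seq) + 1):
                if _matches(r2_seq[off : off + len(tag_seq)], tag_seq, tol):
                    return tag_id
    return None


def count_tags(
    read_pairs: Iterable[tuple[FastqRecord, FastqRecord]],
    tag_reference: Mapping[str, str],
    barcode_spec: BarcodeSpec = BarcodeSpec(),
    mismatch_tolerance: int = 0,
    tag_offset: Optional[int] = None,
) -> TagCountMatrix:
    """Count tag-matching read pairs per (barcode, tag).

    A pair contributes to counts[b, t] when the R1 barcode is b and R2
    carries a match to tag t's sequence (substring search by default, or a
    fixed R2 offset; up to ``mismatch_tolerance`` substitutions).  Pairs
    matching no tag are ignored.  Tags are tried in reference order, so
    overlapping tag sequences must be pairwise distinct (enforced).
    """
    tags = [(str(t), str(s).upper()) for t, s in tag_reference.items()]
    seqs = [s for _, s in tags]
    if len(set(seqs)) != len(seqs):
        raise ValueError("duplicate tag sequences in reference")
    tag_index = {t: j for j, (t, _) in enumerate(tags)}
    bc_index: dict[str, int] = {}
    rows: list[np.ndarray] = []
    for rec1, rec2 in read_pairs:
        hit = _find_tag(rec2.sequence.upper(), tags, mismatch_tolerance, tag_offset)
        if hit is None:
            continue
        bc = barcode_spec.barcode(rec1.sequence)
        i = bc_index.setdefault(bc, len(rows))
        if i == len(rows):
            rows.append(np.zeros(len(tags), dtype=np.int64))
        rows[i][tag_index[hit]] += 1
    counts = np.vstack(rows) if rows else np.zeros((0, len(tags)), dtype=np.int64)
    barcodes = [b for b, _ in sorted(bc_index.items(), key=lambda kv: kv[1])]
    return TagCountMatrix(barcodes=barcodes, tags=[t for t, _ in tags], counts=counts)


def count_tags_from_files(
    r1_path: str,
    r2_path: str,
    tag_reference: Mapping[str, str],
    barcode_spec: BarcodeSpec = BarcodeSpec(),
    **kwargs,
) -> TagCountMatrix:
    return count_tags(
        read_fastq_pairs(r1_path, r2_path), tag_reference, barcode_spec, **kwargs
    )


def assign_tags(m: TagCountMatrix, threshold: float = 0.75) -> pd.DataFrame:
    """Apply the dominant-tag rule to a tag count matrix.

    Per barcode with any tag reads: the barcode is assigned to the argmax tag
    iff that tag's fraction of the barcode's tag reads is >= ``threshold``
    ("at least" 75% by default, so the boundary is inclusive); otherwise it
    is a multiplet.  An argmax tie that still clears the threshold (possible
    only for threshold <= 0.5) is treated as a multiplet.  Barcodes with no
    tag reads are ``undetermined``.

    Returns a DataFrame with columns barcode, status, tag_id,
    dominant_fraction.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    records = []
    for i, bc in enumerate(m.barcodes):
        row = m.counts[i]
        total = int(row.sum())
        if total == 0:
            records.append((bc, STATUS_UNDETERMINED, None, 0.0))
            continue
        top = int(row.max())
        frac = top / total
        if frac >= threshold and int((row == top).sum()) == 1:
            tag = m.tags[int(row.argmax())]
            records.append((bc, STATUS_ASSIGNED, tag, frac))
        else:
            records.append((bc, STATUS_MULTIPLET, None, frac))
    return pd.DataFrame(
        records, columns=["barcode", "status", "tag_id", "dominant_fraction"]
    )


def split_fastq(
    r1_path: str,
    r2_path: str,
    assignment: pd.DataFrame,
    barcode_spec: BarcodeSpec,
    out_dir: str | os.PathLike,
    compress: bool = True,
) -> dict:
    """Split a FASTQ pair into per-tag pairs according to an assignment table.

    Reads whose barcode is assigned to tag t are copied verbatim to
    ``<tag>_R1.fastq[.gz]`` / ``<tag>_R2.fastq[.gz]``; reads from multiplet,
    undetermined or unseen barcodes are dropped.  Returns a manifest with
    per-tag paths and read counts; emitted + dropped equals the input pair
    count.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    tag_of = {
        row.barcode: row.tag_id
        for row in assignment.itertuples()
        if row.status == STATUS_ASSIGNED
    }
    suffix = ".fastq.gz" if compress else ".fastq"
    writers: dict[str, tuple[FastqWriter, FastqWriter]] = {}
    n_emitted: dict[str, int] = {}
    n_dropped = 0
    n_total = 0
    try:
        for rec1, rec2 in read_fastq_pairs(r1_path, r2_path):
            n_total += 1
            tag = tag_of.get(barcode_spec.barcode(rec1.sequence))
            if tag is None:
                n_dropped += 1
                continue
            if tag not in writers:
                w1 = FastqWriter(os.path.join(out_dir, f"{tag}_R1{suffix}"))
                w2 = FastqWriter(os.path.join(out_dir, f"{tag}_R2{suffix}"))
                writers[tag] = (w1, w2)
                n_emitted[tag] = 0
            w1, w2 = writers[tag]
            w1.write(rec1)
            w2.write(rec2)
            n_emitted[tag] += 1
    finally:
        for w1, w2 in writers.values():
            w1.close()
            w2.close()
    for tag, n in sorted(n_emitted.items()):
        log.info("tag %s: %d read pairs", tag, n)
    log.info("dropped %d of %d read pairs", n_dropped, n_total)
    return {
        "files": {
            tag: (
                os.path.join(out_dir, f"{tag}_R1{suffix}"),
                os.path.join(out_dir, f"{tag}_R2{suffix}"),
            )
            for tag in writers
        },
        "emitted": n_emitted,
        "dropped": n_dropped,
        "total": n_total,
    }
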