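"""Donor-specific reference construction.

The base transcriptome carries generic immune-gene transcripts that do not
match any particular donor.  After typing, those transcripts are deleted and
the donor's typed allele cDNA sequences are appended in their place, so that
quantification resolves immune genes at the allele level while all other
genes keep their ordinary transcripts.  The companion lookup table maps each
appended allele to its gene and functional class.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from ._fastq import read_fasta, write_fasta
from .layers import NO_CLASS, AlleleLookupTable

log = logging.getLogger(__name__)

ORIGIN_BASE = "base_transcriptome"
ORIGIN_ALLELE = "typed_allele"

#: default gene -> functional class map (overridable via config)
DEFAULT_CLASS_MAP: dict[str, str] = {
    "HLA-A": "HLA_class_I",
    "HLA-B": "HLA_class_I",
    "HLA-C": "HLA_class_I",
    "HLA-DRA": "HLA_class_II",
    "HLA-DRB1": "HLA_class_II",
    "HLA-DQA1": "HLA_class_II",
    "HLA-DQB1": "HLA_class_II",
    "HLA-DPA1": "HLA_class_II",
    "HLA-DPB1": "HLA_class_II",
}


@dataclass(frozen=True)
class ReferenceRecord:
    feature_id: str
    sequence: str
    origin: str  # ORIGIN_BASE | ORIGIN_ALLELE
    gene_id: str


@dataclass
class DonorReference:
    records: list[ReferenceRecord]
    n_removed: int = 0
    n_appended: int = 0
    n_retained: int = 0

    def __post_init__(self) -> None:
        ids = [r.feature_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate feature ids in donor reference")

    @property
    def feature_ids(self) -> list[str]:
        return [r.feature_id for r in self.records]

    def transcript_gene_map(self) -> dict[str, str]:
        return {r.feature_id: r.gene_id for r in self.records}

    def allele_gene_map(self) -> dict[str, str]:
        return {
            r.feature_id: r.gene_id for r in self.records if r.origin == ORIGIN_ALLELE
        }

    def to_fasta(self, path: str | os.PathLike) -> None:
        write_fasta(path, [(r.feature_id, r.sequence) for r in self.records])


def build_donor_reference(
    base_cdna: Sequence[tuple[str, str]] | str,
    transcript_gene_map: Mapping[str, str],
    immune_gene_ids: Iterable[str],
    typed_alleles: Sequence[tuple[str, str]],
    allele_gene_map: Mapping[str, str],
) -> DonorReference:
    """Replace immune-gene transcripts by the donor's typed allele sequences.

    ``base_cdna`` is a FASTA path or (id, sequence) records; all transcripts
    of genes in ``immune_gene_ids`` are removed (every isoform) and the
    typed allele sequences appended.  Transcripts absent from
    ``transcript_gene_map`` are retained as nonimmune with a warning.
    A typed allele whose gene is not listed as immune raises, since the gene
    would end up represented both by base transcripts and alleles.
    """
    if isinstance(base_cdna, (str, os.PathLike)):
        base_records = [(h.split()[0], s) for h, s in read_fasta(base_cdna)]
    else:
        base_records = [(str(n), s) for n, s in base_cdna]
    immune = {str(g) for g in immune_gene_ids}

    for allele, _ in typed_alleles:
        gene = allele_gene_map.get(allele)
        if gene is None:
            raise ValueError(f"typed allele {allele} missing from allele_gene_map")
        if gene not in immune:
            raise ValueError(
                f"typed allele {allele} belongs to gene {gene} which is not in the "
                "immune gene list; the gene would be represented twice"
            )

    records: list[ReferenceRecord] = []
    n_removed = 0
    for tid, seq in base_records:
        gene = transcript_gene_map.get(tid)
        if gene is None:
            log.warning("transcript %s has no gene mapping; retained as nonimmune", tid)
            gene = tid
        if gene in immune:
            n_removed += 1
            continue
        records.append(ReferenceRecord(tid, seq, ORIGIN_BASE, gene))
    n_retained = len(records)

    typed_genes = {allele_gene_map[a] for a, _ in typed_alleles}
    for gene in sorted(immune - typed_genes):
        log.warning(
            "immune gene %s has no typed alleles; its transcripts were removed and "
            "the gene is unquantifiable in this reference", gene,
        )
    for allele, seq in typed_alleles:
        records.append(ReferenceRecord(allele, seq, ORIGIN_ALLELE, allele_gene_map[allele]))

    return DonorReference(
        records=records,
        n_removed=n_removed,
        n_appended=len(typed_alleles),
        n_retained=n_retained,
    )


def build_lookup(
    allele_gene_map: Mapping[str, str],
    class_map: Optional[Mapping[str, str]] = None,
) -> AlleleLookupTable:
    """One lookup row per typed allele, ordered by (gene, allele name).

    Genes absent from ``class_map`` get functional class ``"none"`` with a
    warning.
    """
    if class_map is None:
        class_map = DEFAULT_CLASS_MAP
    alleles = list(allele_gene_map)
    if len(set(alleles)) != len(alleles):
        raise ValueError("duplicate allele names")
    rows = []
    for allele in sorted(alleles, key=lambda a: (allele_gene_map[a], a)):
        gene = allele_gene_map[allele]
        cls = class_map.get(gene)
        if cls is None:
            log.warning("gene %s absent from class map; functional class '%s'", gene, NO_CLASS)
            cls = NO_CLASS
        rows.append((allele, gene, cls))
    return AlleleLookupTable.from_records(rows)


def read_t2g(path: str | os.PathLike) -> dict[str, str]:
    """Read a 2-column transcript<TAB>gene TSV."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed t2g line: {line!r}")
            out[parts[0]] = parts[1]
    return out


def read_t2g_from_gtf(path: str | os.PathLike) -> dict[str, str]:
    """Minimal GTF reader: transcript -> gene from gene_id/transcript_id attributes."""
    import re

    gene_re = re.compile(r'gene_id "([^"]+)"')
    tx_re = re.compile(r'transcript_id "([^"]+)"')
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            g = gene_re.search(fields[8])
            t = tx_re.search(fields[8])
            if g and t:
                out[t.group(1)] = g.group(1)
    return out
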