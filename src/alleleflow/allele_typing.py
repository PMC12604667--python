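"""HLA allele typing from reads.

Two modes, matching the two single-cell library designs:

* **WTA** (whole-transcriptome): reads are screened against an allele
  database (IMGT-style cDNA sequences).  A read is *compatible* with an
  allele when every database-occurring k-mer of the read occurs in that
  allele; a per-gene multinomial-mixture EM over the compatibility matrix
  then picks the one or two alleles that best explain the reads.  A single
  allele is called (homozygote) when its estimated abundance fraction
  reaches ``homozygote_fraction``.

* **Amplicon**: only the covered part of each target amplicon is
  observable, so reference alleles cannot be resolved.  Reads are grouped
  by their mismatch signature against the amplicon reference; the one or
  two most abundant variant groups are emitted as arbitrary allelic
  variants (``GENE-AV-1``, ``GENE-AV-2``) whose consensus is the reference
  with the group's substitutions applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from ._fastq import read_fasta, write_fasta

log = logging.getLogger(__name__)

MODE_WTA = "wta"
MODE_AMPLICON = "amplicon"

_VALID_ALPHABET = set("ACGTN")


def gene_from_allele_name(allele_name: str) -> str:
    """Gene id for an IMGT-style allele name, e.g. ``A*24:02`` -> ``HLA-A``."""
    prefix = allele_name.split("*")[0]
    return prefix if prefix.startswith("HLA-") else f"HLA-{prefix}"


@dataclass
class AlleleDatabase:
    """Candidate allele cDNA sequences with their gene assignment."""

    names: list[str]
    genes: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("allele names must be unique")
        for name, seq in zip(self.names, self.sequences):
            if not seq:
                raise ValueError(f"empty sequence for allele {name}")
            bad = set(seq.upper()) - _VALID_ALPHABET
            if bad:
                raise ValueError(f"allele {name}: invalid characters {sorted(bad)}")

    @classmethod
    def from_fasta(cls, path: str) -> "AlleleDatabase":
        """Parse an allele FASTA whose headers are ``GENE*NN:NN[...]`` names."""
        names, genes, seqs = [], [], []
        for header, seq in read_fasta(path):
            name = header.split()[0]
            names.append(name)
            genes.append(gene_from_allele_name(name))
            seqs.append(seq)
        return cls(names, genes, seqs)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "AlleleDatabase":
        names, genes, seqs = [], [], []
        for name, gene, seq in records:
            names.append(name)
            genes.append(gene)
            seqs.append(seq.upper())
        return cls(names, genes, seqs)

    def __len__(self) -> int:
        return len(self.names)


@dataclass
class CompatibilityMatrix:
    """reads x alleles boolean compatibility with per-allele gene labels."""

    matrix: np.ndarray  # (n_reads, n_alleles) bool; all-false rows dropped
    allele_names: list[str]
    allele_genes: list[str]
    n_input_reads: int
    n_dropped: int


@dataclass
class TypingResult:
    """Per-gene typed alleles with estimated abundance fractions."""

    mode: str
    genes: dict[str, list[tuple[str, float]]] = field(default_factory=dict)
    consensi: dict[str, str] = field(default_factory=dict)  # amplicon AV sequences

    def allele_gene_map(self) -> dict[str, str]:
        return {a: g for g, alleles in self.genes.items() for a, _ in alleles}

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "genes": {
                g: [{"allele": a, "fraction": f} for a, f in alleles]
                for g, alleles in self.genes.items()
            },
        }


def _kmers(seq: str, k: int) -> Iterable[str]:
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if "N" not in km:
            yield km


def build_compatibility(
    reads: Sequence[str], db: AlleleDatabase, k: int = 31
) -> CompatibilityMatrix:
    """Screen reads against the allele database with the k-mer intersection rule.

    A read is compatible with allele *a* iff every k-mer of the read that
    occurs anywhere in the database also occurs in *a* (k-mers absent from
    the database carry no information and are skipped, which makes the rule
    robust to sequencing errors).  Reads with no database k-mer, or whose
    informative k-mers are jointly incompatible with every allele, are
    dropped.
    """
    if not (11 <= k <= 31) or k % 2 == 0:
        raise ValueError("k must be odd and within [11, 31]")
    n_alleles = len(db)
    kmer_map: dict[str, np.ndarray] = {}
    sets: dict[str, set[int]] = {}
    for j, seq in enumerate(db.sequences):
        for km in _kmers(seq.upper(), k):
            sets.setdefault(km, set()).add(j)
    for km, s in sets.items():
        mask = np.zeros(n_alleles, dtype=bool)
        mask[list(s)] = True
        kmer_map[km] = mask
    del sets

    rows = []
    dropped = 0
    for read in reads:
        read = read.upper()
        if len(read) < k:
            raise ValueError(f"read shorter than k={k}")
        compat: Optional[np.ndarray] = None
        for km in _kmers(read, k):
            mask = kmer_map.get(km)
            if mask is None:
                continue
            compat = mask.copy() if compat is None else (compat & mask)
            if not compat.any():
                break
        if compat is None or not compat.any():
            dropped += 1
            continue
        rows.append(compat)
    matrix = np.vstack(rows) if rows else np.zeros((0, n_alleles), dtype=bool)
    return CompatibilityMatrix(
        matrix=matrix,
        allele_names=list(db.names),
        allele_genes=list(db.genes),
        n_input_reads=len(reads),
        n_dropped=dropped,
    )


def _em_fractions(
    compat: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, list[float]]:
    """Multinomial-mixture EM over a boolean reads x alleles matrix.

    Returns the abundance vector theta and the per-iteration log-likelihood
    trace (non-decreasing by EM construction).
    """
    n_reads, n_alleles = compat.shape
    c = compat.astype(float)
    theta = np.full(n_alleles, 1.0 / n_alleles)
    trace: list[float] = []
    for _ in range(max_iter):
        # E-step: fractional assignment of each read over compatible alleles
        w = c * theta
        row_sums = w.sum(axis=1)
        trace.append(float(np.log(row_sums).sum()))
        w /= row_sums[:, None]
        # M-step
        new_theta = w.sum(axis=0) / n_reads
        delta = float(np.max(np.abs(new_theta - theta)))
        theta = new_theta
        if delta < tol:
            trace.append(float(np.log((c * theta).sum(axis=1)).sum()))
            break
    return theta, trace


def em_select_alleles(
    c: CompatibilityMatrix,
    max_per_gene: int = 2,
    tol: float = 1e-6,
    max_iter: int = 1000,
    homozygote_fraction: float = 0.85,
) -> TypingResult:
    """Pick the 1 or 2 most abundant alleles per gene by EM.

    EM runs per gene over the reads relevant to that gene (a read whose
    compatible alleles span several genes enters each such gene's EM with
    its set restricted to that gene's alleles).  The top allele is reported
    alone when its fraction reaches ``homozygote_fraction``; otherwise the
    top ``max_per_gene`` alleles are reported.  Ties in theta are broken by
    allele-name lexicographic order, so the result is deterministic.
    """
    if c.matrix.shape[0] == 0:
        raise ValueError("compatibility matrix is empty")
    genes = sorted(set(c.allele_genes))
    gene_arr = np.asarray(c.allele_genes, dtype=object)
    result = TypingResult(mode=MODE_WTA)
    for gene in genes:
        cols = np.where(gene_arr == gene)[0]
        sub = c.matrix[:, cols]
        rows = sub.any(axis=1)
        if not rows.any():
            log.warning("no reads for gene %s; gene absent from typing result", gene)
            continue
        sub = sub[rows]
        theta, trace = _em_fractions(sub, tol=tol, max_iter=max_iter)
        names = [c.allele_names[j] for j in cols]
        # deterministic ordering: theta descending, name ascending
        order = sorted(range(len(names)), key=lambda j: (-theta[j], names[j]))
        top = order[0]
        if theta[top] >= homozygote_fraction:
            chosen = [top]
        else:
            chosen = order[:max_per_gene]
        result.genes[gene] = [(names[j], float(theta[j])) for j in chosen]
    return result


# ---------------------------------------------------------------------------
# amplicon mode
# ---------------------------------------------------------------------------


def _kmer_positions(seq: str, k: int) -> dict[str, int]:
    out: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km not in out:
            out[km] = i
    return out


def _assign_to_amplicon(
    read: str, refs: dict[str, dict[str, int]], k: int
) -> Optional[str]:
    """Best amplicon by k-mer containment; ties resolved lexicographically."""
    best, best_hits = None, 0
    for amp_id in sorted(refs):
        pos = refs[amp_id]
        hits = sum(1 for km in _kmers(read, k) if km in pos)
        if hits > best_hits:
            best, best_hits = amp_id, hits
    return best


def _locate(read: str, ref_pos: dict[str, int], ref_len: int, k: int) -> Optional[int]:
    """Ungapped offset of the read on the reference via the first seed k-mer."""
    for i in range(len(read) - k + 1):
        p = ref_pos.get(read[i : i + k])
        if p is not None:
            off = p - i
            if 0 <= off and off + len(read) <= ref_len:
                return off
    return None


def amplicon_variant_typing(
    reads: Sequence[str],
    amplicon_ref: Mapping[str, str],
    min_minor_fraction: float = 0.25,
    min_variant_reads: int = 10,
    k: int = 21,
) -> TypingResult:
    """Infer the one or two most abundant transcript variants per amplicon.

    Reads are assigned to their best-matching amplicon, located on it by a
    seed k-mer, and grouped by mismatch signature (the set of
    (position, base) substitutions over the read's covered positions); reads
    with identical covered-position base calls share a signature.  Groups
    smaller than ``min_variant_reads`` are discarded as sequencing-error
    singletons.  The top group becomes ``GENE-AV-1``; the runner-up becomes
    ``GENE-AV-2`` iff its read count is at least ``min_minor_fraction`` of
    the top count.  AV identifiers are arbitrary: they carry no allele
    registry meaning.
    """
    refs = {str(a): s.upper() for a, s in amplicon_ref.items()}
    ref_pos = {a: _kmer_positions(s, k) for a, s in refs.items()}
    groups: dict[str, dict[frozenset, int]] = {a: {} for a in refs}
    n_assigned: dict[str, int] = {a: 0 for a in refs}
    for read in reads:
        read = read.upper()
        amp = _assign_to_amplicon(read, ref_pos, k)
        if amp is None:
            continue
        ref = refs[amp]
        off = _locate(read, ref_pos[amp], len(ref), k)
        if off is None:
            continue
        sig = frozenset(
            (off + i, b) for i, b in enumerate(read) if b != ref[off + i]
        )
        groups[amp][sig] = groups[amp].get(sig, 0) + 1
        n_assigned[amp] += 1

    result = TypingResult(mode=MODE_AMPLICON)
    for amp in sorted(refs):
        if n_assigned[amp] < min_variant_reads:
            log.warning(
                "amplicon %s: only %d reads (< %d); skipped",
                amp, n_assigned[amp], min_variant_reads,
            )
            continue
        kept = {s: n for s, n in groups[amp].items() if n >= min_variant_reads}
        if not kept:
            log.warning("amplicon %s: no variant group passes the read filter", amp)
            continue
        # rank by count desc, then smallest signature, then lexicographic
        ranked = sorted(
            kept.items(), key=lambda kv: (-kv[1], len(kv[0]), sorted(kv[0]))
        )
        total = sum(n for _, n in ranked)
        chosen = [ranked[0]]
        if len(ranked) > 1 and ranked[1][1] >= min_minor_fraction * ranked[0][1]:
            chosen.append(ranked[1])
        alleles = []
        for idx, (sig, n) in enumerate(chosen, start=1):
            name = f"{amp}-AV-{idx}"
            seq = list(refs[amp])
            for pos, base in sig:
                seq[pos] = base
            result.consensi[name] = "".join(seq)
            alleles.append((name, n / total))
        result.genes[amp] = alleles
    return result


def typing_to_fasta(
    t: TypingResult,
    db_or_consensi: AlleleDatabase | Mapping[str, str] | None = None,
    out_path: Optional[str] = None,
) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Resolve typed alleles to sequences; optionally write a FASTA.

    Returns (records, allele -> gene map).  WTA results resolve against the
    allele database; amplicon results carry their own consensus sequences.
    """
    seq_of: dict[str, str] = dict(t.consensi)
    if isinstance(db_or_consensi, AlleleDatabase):
        seq_of.update(zip(db_or_consensi.names, db_or_consensi.sequences))
    elif db_or_consensi is not None:
        seq_of.update(db_or_consensi)
    records: list[tuple[str, str]] = []
    gene_map: dict[str, str] = {}
    for gene in sorted(t.genes):
        for allele, _ in t.genes[gene]:
            if allele not in seq_of:
                raise ValueError(f"typed allele {allele} has no resolvable sequence")
            records.append((allele, seq_of[allele]))
            gene_map[allele] = gene
    if not records:
        log.warning("typing result is empty; writing empty FASTA")
    if out_path is not None:
        write_fasta(out_path, records)
    return records, gene_map


def em_loglik(compat: np.ndarray, theta: np.ndarray) -> float:
    """Log-likelihood of abundances theta under the compatibility mixture."""
    per_read = (compat.astype(float) * theta).sum(axis=1)
    return float(np.sum(np.log(per_read)))
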