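"""Alignment-free quantification with explicit multimapping handling.

Donor references contain two near-identical allele sequences per immune
gene, so reads routinely pseudo-align to several transcripts.  Discarding
such reads would systematically underestimate allele expression; instead
they are kept (the multimapping-aware mode of pseudoalignment counters) and
their counts distributed by EM:

1. a canonical k-mer index maps each read to the set of transcripts
   compatible with all of its indexed k-mers (its equivalence class);
2. (barcode, UMI) duplicates collapse to a single molecule;
3. EM over transcript proportions splits each equivalence-class count among
   its member transcripts; proportions are estimated on the pooled counts
   of all cells by default and then applied per cell, which conserves each
   cell's total UMI count exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._fastq import read_fastq_pairs
from .demux import BarcodeSpec
from .reference import ORIGIN_ALLELE, DonorReference

log = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

POOL_ALL = "all_cells"
POOL_PER_CELL = "per_cell"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class KmerIndex:
    k: int
    kmer_map: dict[str, frozenset[int]]
    transcript_ids: list[str]
    transcript_lengths: list[int]


def index_reference(
    ref: DonorReference | Sequence[tuple[str, str]], k: int = 31
) -> KmerIndex:
    """Canonical k-mer -> transcript-set index (k-mers containing N skipped)."""
    if k % 2 == 0:
        raise ValueError("k must be odd (canonical k-mers need no palindromes)")
    if isinstance(ref, DonorReference):
        records = [(r.feature_id, r.sequence) for r in ref.records]
    else:
        records = [(str(n), s) for n, s in ref]
    if not records:
        raise ValueError("cannot index an empty reference")
    tmp: dict[str, set[int]] = {}
    ids, lengths = [], []
    for idx, (tid, seq) in enumerate(records):
        seq = seq.upper()
        ids.append(tid)
        lengths.append(len(seq))
        if len(seq) < k:
            log.warning("transcript %s shorter than k=%d; indexed with 0 k-mers", tid, k)
            continue
        for i in range(len(seq) - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            tmp.setdefault(canonical(km), set()).add(idx)
    return KmerIndex(
        k=k,
        kmer_map={km: frozenset(s) for km, s in tmp.items()},
        transcript_ids=ids,
        transcript_lengths=lengths,
    )


def pseudoalign(read_seq: str, index: KmerIndex) -> Optional[frozenset[int]]:
    """Equivalence class of a read: intersection over its indexed k-mers.

    k-mers absent from the index are skipped (treated as errors); a read
    whose indexed k-mers have an empty joint intersection is incompatible
    and returns None, as does a read with no indexed k-mer at all.
    """
    k = index.k
    read_seq = read_seq.upper()
    ec: Optional[frozenset[int]] = None
    for i in range(len(read_seq) - k + 1):
        km = read_seq[i : i + k]
        if "N" in km:
            continue
        hit = index.kmer_map.get(canonical(km))
        if hit is None:
            continue
        ec = hit if ec is None else (ec & hit)
        if not ec:
            return None
    return ec if ec else None


def collapse_umis(
    records: Iterable[tuple[str, str, frozenset[int]]],
) -> dict[str, dict[tuple[int, ...], int]]:
    """Deduplicate (barcode, UMI) pairs into per-barcode equivalence-class counts.

    Duplicates of one molecule collapse to a single count placed on the
    intersection of their equivalence classes when non-empty; otherwise on
    the most frequent class among the duplicates, ties going to the
    lexicographically smallest set.  The per-barcode total therefore equals
    the number of distinct retained (barcode, UMI) pairs.
    """
    per_molecule: dict[tuple[str, str], list[frozenset[int]]] = {}
    for bc, umi, ec in records:
        per_molecule.setdefault((bc, umi), []).append(ec)
    out: dict[str, dict[tuple[int, ...], int]] = {}
    for (bc, _umi), ecs in per_molecule.items():
        inter = frozenset.intersection(*ecs)
        if inter:
            chosen = tuple(sorted(inter))
        else:
            freq: dict[tuple[int, ...], int] = {}
            for ec in ecs:
                key = tuple(sorted(ec))
                freq[key] = freq.get(key, 0) + 1
            best = max(freq.values())
            chosen = min(k for k, v in freq.items() if v == best)
        cell = out.setdefault(bc, {})
        cell[chosen] = cell.get(chosen, 0) + 1
    return out


def _em_theta(
    ec_sets: list[tuple[int, ...]],
    ec_counts: np.ndarray,
    n_transcripts: int,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, list[float]]:
    """EM for transcript proportions theta given equivalence-class counts."""
    # membership matrix (n_ecs, n_transcripts), sparse-ish but tiny in practice
    m = np.zeros((len(ec_sets), n_transcripts))
    for i, ec in enumerate(ec_sets):
        m[i, list(ec)] = 1.0
    theta = np.full(n_transcripts, 1.0 / n_transcripts)
    total = float(ec_counts.sum())
    trace: list[float] = []
    for _ in range(max_iter):
        denom = m @ theta
        trace.append(float(np.dot(ec_counts, np.log(denom))))
        # E-step: expected counts per transcript
        resp = (m * theta) / denom[:, None]
        expected = ec_counts @ resp
        new_theta = expected / total
        delta = float(np.max(np.abs(new_theta - theta)))
        theta = new_theta
        if delta < tol:
            trace.append(float(np.dot(ec_counts, np.log(m @ theta))))
            break
    return theta, trace


def _distribute(
    cell_ecs: Mapping[tuple[int, ...], int], theta: np.ndarray, n_transcripts: int
) -> np.ndarray:
    """Split one cell's ec counts among transcripts proportional to theta."""
    row = np.zeros(n_transcripts)
    for ec, count in cell_ecs.items():
        idx = np.fromiter(ec, dtype=int)
        w = theta[idx]
        s = w.sum()
        if s <= 0:
            w = np.full(len(idx), 1.0 / len(idx))
        else:
            w = w / s
        row[idx] += count * w
    return row


def em_distribute(
    ecs_per_barcode: Mapping[str, Mapping[tuple[int, ...], int]],
    n_transcripts: int,
    tol: float = 1e-8,
    max_iter: int = 1000,
    pool: str = POOL_ALL,
    uniform_split: bool = False,
) -> tuple[sp.csr_matrix, list[str]]:
    """Distribute equivalence-class counts over transcripts.

    ``pool="all_cells"`` (default) estimates one proportion vector theta on
    the pooled counts of all barcodes, then distributes each barcode's
    counts with theta restricted to each class's transcript set;
    ``pool="per_cell"`` runs EM independently per barcode.
    ``uniform_split=True`` skips EM and splits every class uniformly over
    its transcripts (the naive multimapping treatment, kept for
    comparison).  Per-cell totals are conserved exactly in every mode.
    """
    barcodes = list(ecs_per_barcode)
    rows = []
    for bc in barcodes:
        for ec in ecs_per_barcode[bc]:
            for t in ec:
                if not 0 <= t < n_transcripts:
                    raise ValueError(f"transcript index {t} out of range")
    if uniform_split:
        theta_global = np.full(n_transcripts, 1.0 / n_transcripts)
        for bc in barcodes:
            rows.append(_distribute(ecs_per_barcode[bc], theta_global, n_transcripts))
    elif pool == POOL_ALL:
        pooled: dict[tuple[int, ...], int] = {}
        for bc in barcodes:
            for ec, n in ecs_per_barcode[bc].items():
                pooled[ec] = pooled.get(ec, 0) + n
        if pooled:
            ec_sets = list(pooled)
            counts = np.array([pooled[e] for e in ec_sets], dtype=float)
            theta, _ = _em_theta(ec_sets, counts, n_transcripts, tol, max_iter)
        else:
            theta = np.full(n_transcripts, 1.0 / n_transcripts)
        for bc in barcodes:
            rows.append(_distribute(ecs_per_barcode[bc], theta, n_transcripts))
    elif pool == POOL_PER_CELL:
        for bc in barcodes:
            cell = ecs_per_barcode[bc]
            if cell:
                ec_sets = list(cell)
                counts = np.array([cell[e] for e in ec_sets], dtype=float)
                theta, _ = _em_theta(ec_sets, counts, n_transcripts, tol, max_iter)
            else:
                theta = np.full(n_transcripts, 1.0 / n_transcripts)
            rows.append(_distribute(cell, theta, n_transcripts))
    else:
        raise ValueError(f"unknown pool mode: {pool}")
    mat = np.vstack(rows) if rows else np.zeros((0, n_transcripts))
    return sp.csr_matrix(mat), barcodes


def quantify_run(
    r1_path: str,
    r2_path: str,
    ref: DonorReference,
    barcode_spec: BarcodeSpec = BarcodeSpec(),
    k: int = 31,
    tol: float = 1e-8,
    max_iter: int = 1000,
    pool: str = POOL_ALL,
    uniform_split: bool = False,
) -> tuple[sp.csr_matrix, list[str], list[str], pd.DataFrame]:
    """Full quantification of a FASTQ pair against a donor reference.

    Pipeline: pseudoalign R2 reads -> collapse (barcode, UMI) duplicates ->
    EM-distribute equivalence-class counts.  Transcript-level expected
    counts of nonimmune (base-transcriptome) transcripts are summed into
    their genes, so the returned base features are nonimmune genes followed
    by alleles, in reference order of first appearance.

    Returns (base_counts, barcodes, base_feature_ids, feature_table).
    """
    index = index_reference(ref, k=k)

    def stream():
        for rec1, rec2 in read_fastq_pairs(r1_path, r2_path):
            if len(rec2.sequence) < k:
                continue
            ec = pseudoalign(rec2.sequence, index)
            if ec is None:
                continue
            yield barcode_spec.barcode(rec1.sequence), barcode_spec.umi(rec1.sequence), ec

    ecs = collapse_umis(stream())
    abundance, barcodes = em_distribute(
        ecs, len(index.transcript_ids), tol=tol, max_iter=max_iter,
        pool=pool, uniform_split=uniform_split,
    )

    # collapse nonimmune transcripts to genes; alleles stay allele-level
    features: list[str] = []
    layer_kind: list[str] = []
    col_of: dict[str, int] = {}
    src_cols: list[list[int]] = []
    for j, rec in enumerate(ref.records):
        fid = rec.gene_id if rec.origin != ORIGIN_ALLELE else rec.feature_id
        if fid not in col_of:
            col_of[fid] = len(features)
            features.append(fid)
            layer_kind.append("allele" if rec.origin == ORIGIN_ALLELE else "nonimmune_gene")
            src_cols.append([])
        src_cols[col_of[fid]].append(j)
    dense = np.asarray(abundance.todense())
    base = np.zeros((dense.shape[0], len(features)))
    for out_col, cols in enumerate(src_cols):
        base[:, out_col] = dense[:, cols].sum(axis=1)
    feature_table = pd.DataFrame({"feature_id": features, "kind": layer_kind})
    return sp.csr_matrix(base), barcodes, features, feature_table
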