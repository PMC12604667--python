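"""Synthetic data generators for the whole pipeline.

Every generator is a pure function of (parameters, seed) and emits a truth
manifest alongside its reads, so any downstream stage can be scored against
known ground truth without re-derivation.  The generators emulate the study
conditions the pipeline targets: allele pairs at controlled pairwise
divergence, per-cell barcoded/UMI-tagged reads at known allele ratios,
sample-tag reads for multiplexed runs, and a two-population (cells vs
ambient) barcode model for knee-filter evaluation.

The error model is substitution-only with uniform read-start positions; no
indels and no quality-score modelling (constant Q).  A 3'-concentration
option places allele differences away from the poly-A end, emulating the
poly-A-proximal sequence similarity that limits allele discrimination in 3'
chemistry.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from ._fastq import FastqRecord, write_fastq
from .demux import BarcodeSpec

BASES = np.array(list("ACGT"))


@dataclass
class SimulationTruth:
    """Ground truth accompanying a simulated dataset."""

    seed: int
    genotype: dict[str, list[str]] = field(default_factory=dict)  # gene -> allele names
    cell_proportions: dict[str, dict[str, float]] = field(default_factory=dict)
    barcode_tag: dict[str, str] = field(default_factory=dict)
    ambient_barcodes: list[str] = field(default_factory=list)

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "genotype": self.genotype,
                    "cell_proportions": self.cell_proportions,
                    "barcode_tag": self.barcode_tag,
                    "ambient_barcodes": self.ambient_barcodes,
                },
                fh,
                indent=2,
            )


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(BASES, size=length))


def make_allele_set(
    gene_id: str,
    length: int,
    n_alleles: int,
    substitutions_per_allele: int,
    seed: int,
    avoid_three_prime: bool = False,
) -> tuple[dict[str, str], str]:
    """Generate allele sequences at controlled pairwise divergence.

    A base sequence is drawn i.i.d. uniform over ACGT; each allele carries
    ``substitutions_per_allele`` substitutions at positions disjoint across
    alleles, so any two alleles differ at exactly 2 x substitutions
    positions.  With ``avoid_three_prime`` the substituted positions are
    confined to the first 80% of the sequence, keeping the 3' (poly-A
    proximal) end identical across alleles.

    Returns ({allele_name: sequence}, base_sequence); allele names are
    ``GENE*SIM:01`` style.
    """
    rng = np.random.default_rng(seed)
    total = n_alleles * substitutions_per_allele
    limit = int(length * 0.8) if avoid_three_prime else length
    if total > limit:
        raise ValueError(
            f"cannot place {total} disjoint substitutions in {limit} positions"
        )
    base = random_sequence(length, rng)
    positions = rng.choice(limit, size=total, replace=False)
    alleles: dict[str, str] = {}
    short = gene_id.replace("HLA-", "")
    for i in range(n_alleles):
        seq = list(base)
        for p in positions[
            i * substitutions_per_allele : (i + 1) * substitutions_per_allele
        ]:
            current = seq[p]
            choices = [b for b in "ACGT" if b != current]
            seq[p] = choices[rng.integers(len(choices))]
        alleles[f"{short}*SIM:{i + 1:02d}"] = "".join(seq)
    return alleles, base


def _mutate(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
    hits = np.where(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return "".join(arr)


def make_barcodes(n: int, length: int, rng: np.random.Generator) -> list[str]:
    out: set[str] = set()
    while len(out) < n:
        out.add("".join(rng.choice(BASES, size=length)))
    return sorted(out)


def simulate_cell_reads(
    transcripts: Mapping[str, str],
    proportions: Mapping[str, Mapping[str, float]],
    umis_per_cell: int,
    read_len: int,
    error_rate: float,
    seed: int,
    barcode_spec: BarcodeSpec = BarcodeSpec(),
    r1_path: Optional[str] = None,
    r2_path: Optional[str] = None,
) -> tuple[list[FastqRecord], list[FastqRecord], SimulationTruth]:
    """Simulate barcoded, UMI-tagged cDNA read pairs at known feature ratios.

    ``proportions`` maps barcode -> {feature: proportion} (per cell summing
    to 1).  Per cell, UMI counts per feature are multinomial; each UMI emits
    one read from a uniform start position on its transcript with
    independent per-base substitution errors.  R1 = barcode + UMI (padded
    with A to cover the spec); R2 = the cDNA read.  Byte-reproducible for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    barcodes = list(proportions)
    if len(set(barcodes)) != len(barcodes):
        raise ValueError("duplicate barcodes requested")
    min_len = min(len(s) for s in transcripts.values())
    if read_len > min_len:
        raise ValueError("read_len exceeds the shortest transcript")
    r1_len = barcode_spec.umi_start + barcode_spec.umi_len
    truth = SimulationTruth(seed=seed)
    r1_records: list[FastqRecord] = []
    r2_records: list[FastqRecord] = []
    n_read = 0
    for bc in barcodes:
        props = proportions[bc]
        feats = sorted(props)
        p = np.array([props[f] for f in feats], dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"proportions for {bc} do not sum to 1")
        truth.cell_proportions[bc] = {f: float(v) for f, v in zip(feats, p)}
        counts = rng.multinomial(umis_per_cell, p)
        for feat, n_umis in zip(feats, counts):
            seq = transcripts[feat]
            for _ in range(int(n_umis)):
                umi = "".join(rng.choice(BASES, size=barcode_spec.umi_len))
                start = int(rng.integers(0, len(seq) - read_len + 1))
                read = _mutate(seq[start : start + read_len], error_rate, rng)
                r1 = (bc + umi).ljust(r1_len, "A")
                name = f"sim.{n_read}"
                r1_records.append(FastqRecord(name, r1, "I" * len(r1)))
                r2_records.append(FastqRecord(name, read, "I" * len(read)))
                n_read += 1
    if r1_path:
        write_fastq(r1_path, r1_records)
    if r2_path:
        write_fastq(r2_path, r2_records)
    return r1_records, r2_records, truth


def simulate_tag_reads(
    barcode_tag: Mapping[str, str],
    tag_sequences: Mapping[str, str],
    reads_per_cell: int,
    contamination_rate: float,
    seed: int,
    barcode_spec: BarcodeSpec = BarcodeSpec(),
    doublet_barcodes: Optional[Mapping[str, tuple[str, str]]] = None,
    r1_path: Optional[str] = None,
    r2_path: Optional[str] = None,
    read_len: int = 60,
) -> tuple[list[FastqRecord], list[FastqRecord], SimulationTruth]:
    """Simulate sample-tag read pairs per barcode.

    Each singlet barcode draws its true tag with probability
    1 - contamination_rate and a uniform other tag otherwise; barcodes in
    ``doublet_barcodes`` draw 50/50 from their two tags.  R2 carries the tag
    sequence padded with A to ``read_len``.
    """
    if not 0 <= contamination_rate < 0.5:
        raise ValueError("contamination_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    tags = sorted(tag_sequences)
    doublets = dict(doublet_barcodes or {})
    truth = SimulationTruth(seed=seed, barcode_tag=dict(barcode_tag))
    r1_records: list[FastqRecord] = []
    r2_records: list[FastqRecord] = []
    r1_len = barcode_spec.umi_start + barcode_spec.umi_len
    n_read = 0
    all_barcodes = list(barcode_tag) + [b for b in doublets if b not in barcode_tag]
    for bc in all_barcodes:
        for _ in range(reads_per_cell):
            if bc in doublets:
                pair = doublets[bc]
                tag = pair[int(rng.integers(2))]
            else:
                true = barcode_tag[bc]
                if rng.random() < contamination_rate:
                    others = [t for t in tags if t != true]
                    tag = others[int(rng.integers(len(others)))]
                else:
                    tag = true
            umi = "".join(rng.choice(BASES, size=barcode_spec.umi_len))
            r1 = (bc + umi).ljust(r1_len, "A")
            r2 = tag_sequences[tag].ljust(read_len, "A")
            name = f"tag.{n_read}"
            r1_records.append(FastqRecord(name, r1, "I" * len(r1)))
            r2_records.append(FastqRecord(name, r2, "I" * len(r2)))
            n_read += 1
    if r1_path:
        write_fastq(r1_path, r1_records)
    if r2_path:
        write_fastq(r2_path, r2_records)
    return r1_records, r2_records, truth


def simulate_ambient_barcodes(
    n_cells: int,
    n_ambient: int,
    cell_mean: float,
    ambient_mean: float,
    seed: int,
    dispersion: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-population barcode totals for knee-filter evaluation.

    Totals are negative binomial with var = mean + dispersion * mean^2
    (dispersion 0.5, i.e. size r = 2); returns (totals, is_cell labels)
    with cells first.
    """
    if cell_mean <= ambient_mean:
        raise ValueError("cell_mean must exceed ambient_mean")
    rng = np.random.default_rng(seed)
    r = 1.0 / dispersion

    def draw(mean: float, n: int) -> np.ndarray:
        p = r / (r + mean)
        return rng.negative_binomial(r, p, size=n)

    totals = np.concatenate([draw(cell_mean, n_cells), draw(ambient_mean, n_ambient)])
    labels = np.concatenate(
        [np.ones(n_cells, dtype=bool), np.zeros(n_ambient, dtype=bool)]
    )
    return totals, labels


def simulate_multiplexed_run(
    n_donors: int,
    genes: Sequence[str],
    cells_per_donor: int,
    umis_per_cell: int,
    seed: int,
    allele_length: int = 600,
    substitutions_per_allele: int = 6,
    n_decoy_alleles_per_gene: int = 3,
    nonimmune_genes: Sequence[str] = ("GAPDH", "ACTB"),
    read_len: int = 90,
    error_rate: float = 0.001,
    tag_reads_per_cell: int = 30,
    barcode_spec: BarcodeSpec = BarcodeSpec(),
    out_dir: Optional[str] = None,
) -> dict:
    """Compose a full multiplexed study: tags + cDNA reads + references + truth.

    Each donor gets a heterozygous genotype (two alleles per immune gene)
    drawn from a shared allele database that also contains decoy alleles.
    Cells split base-layer expression evenly across nonimmune genes and
    immune genes, with a 50/50 allele split within each gene.  Tag reads and
    cDNA reads are interleaved in one FASTQ pair, as in a real multiplexed
    library.  Returns a bundle with paths/records, the allele database,
    reference files and per-donor truth.
    """
    rng = np.random.default_rng(seed)
    n_candidates = 2 + n_decoy_alleles_per_gene
    db_records: list[tuple[str, str, str]] = []
    genotype: dict[int, dict[str, list[str]]] = {d: {} for d in range(n_donors)}
    allele_seqs: dict[str, str] = {}
    for gene in genes:
        alleles, _ = make_allele_set(
            gene, allele_length, n_candidates, substitutions_per_allele,
            seed=int(rng.integers(2**31)),
        )
        names = sorted(alleles)
        for name in names:
            db_records.append((name, gene, alleles[name]))
            allele_seqs[name] = alleles[name]
        for d in range(n_donors):
            pick = rng.choice(len(names), size=2, replace=False)
            genotype[d][gene] = sorted(names[i] for i in pick)

    nonimmune_seqs = {
        g: random_sequence(allele_length, rng) for g in nonimmune_genes
    }
    tag_ids = [f"ST{d + 1}" for d in range(n_donors)]
    tag_sequences = {t: random_sequence(40, rng) for t in tag_ids}

    barcodes = make_barcodes(
        n_donors * cells_per_donor, barcode_spec.bc_len, rng
    )
    barcode_tag: dict[str, str] = {}
    donor_of: dict[str, int] = {}
    for i, bc in enumerate(barcodes):
        d = i % n_donors
        barcode_tag[bc] = tag_ids[d]
        donor_of[bc] = d

    # per-cell proportions: nonimmune genes and immune genes share the budget
    # equally; alleles within a gene split 50/50
    proportions: dict[str, dict[str, float]] = {}
    n_feats = len(nonimmune_genes) + len(genes)
    for bc in barcodes:
        d = donor_of[bc]
        props: dict[str, float] = {}
        for g in nonimmune_genes:
            props[g] = 1.0 / n_feats
        for gene in genes:
            a1, a2 = genotype[d][gene]
            props[a1] = 0.5 / n_feats
            props[a2] = 0.5 / n_feats
        proportions[bc] = props

    transcripts = dict(nonimmune_seqs)
    transcripts.update(allele_seqs)
    r1_cdna, r2_cdna, truth_cells = simulate_cell_reads(
        transcripts, proportions, umis_per_cell, read_len, error_rate,
        seed=int(rng.integers(2**31)), barcode_spec=barcode_spec,
    )
    r1_tags, r2_tags, _ = simulate_tag_reads(
        barcode_tag, tag_sequences, tag_reads_per_cell, 0.0,
        seed=int(rng.integers(2**31)), barcode_spec=barcode_spec,
        read_len=read_len,
    )
    # interleave deterministically: tags first, then cDNA (order is irrelevant
    # to every consumer, which keys on barcode)
    r1_all = r1_tags + r1_cdna
    r2_all = r2_tags + r2_cdna

    truth = SimulationTruth(
        seed=seed,
        genotype={f"donor{d}": {g: genotype[d][g] for g in genes} for d in range(n_donors)},
        cell_proportions=truth_cells.cell_proportions,
        barcode_tag=barcode_tag,
    )
    bundle = {
        "r1_records": r1_all,
        "r2_records": r2_all,
        "tag_sequences": tag_sequences,
        "tag_of_donor": {f"donor{d}": tag_ids[d] for d in range(n_donors)},
        "db_records": db_records,
        "nonimmune_seqs": nonimmune_seqs,
        "genes": list(genes),
        "truth": truth,
        "barcode_spec": barcode_spec,
    }
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        from ._fastq import write_fasta

        bundle["r1_path"] = os.path.join(out_dir, "R1.fastq.gz")
        bundle["r2_path"] = os.path.join(out_dir, "R2.fastq.gz")
        write_fastq(bundle["r1_path"], r1_all)
        write_fastq(bundle["r2_path"], r2_all)
        bundle["tags_path"] = os.path.join(out_dir, "tags.fa")
        write_fasta(bundle["tags_path"], sorted(tag_sequences.items()))
        bundle["db_path"] = os.path.join(out_dir, "allele_db.fa")
        write_fasta(bundle["db_path"], [(n, s) for n, _, s in db_records])
        base_records = [(f"{g}-tx1", s) for g, s in sorted(nonimmune_seqs.items())]
        # base transcriptome: nonimmune transcripts plus one generic immune
        # transcript per gene (the first database allele stands in for the
        # generic reference sequence)
        first_of_gene: dict[str, str] = {}
        for name, gene, seq in db_records:
            first_of_gene.setdefault(gene, seq)
        for gene in genes:
            base_records.append((f"{gene}-tx1", first_of_gene[gene]))
        bundle["base_cdna_path"] = os.path.join(out_dir, "base_cdna.fa")
        write_fasta(bundle["base_cdna_path"], base_records)
        bundle["t2g_path"] = os.path.join(out_dir, "t2g.tsv")
        with open(bundle["t2g_path"], "w") as fh:
            for g in sorted(nonimmune_seqs):
                fh.write(f"{g}-tx1\t{g}\n")
            for gene in genes:
                fh.write(f"{gene}-tx1\t{gene}\n")
        truth.to_json(os.path.join(out_dir, "truth.json"))
    return bundle
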