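"""End-to-end orchestration: demux -> typing -> reference -> quantify -> QC.

Each stage logs to ``out_dir/logs/<stage>.log``; per-donor outputs land in
``out_dir/<donor>/`` and a JSON manifest lists, per donor, the four files
downstream analysis needs: the counts matrix, barcodes, features (with
layer column) and the lookup CSV.
"""

from __future__ import annotations

import json
import logging
import os
from typing import Optional

from . import demux as dmx
from . import qc as qcmod
from ._fastq import read_fasta
from .allele_typing import (
    AlleleDatabase,
    amplicon_variant_typing,
    build_compatibility,
    em_select_alleles,
    typing_to_fasta,
)
from .config import RunConfig
from .layers import build_multilayer, write_experiment
from .quantify import quantify_run
from .reference import (
    DEFAULT_CLASS_MAP,
    build_donor_reference,
    build_lookup,
    read_t2g,
)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


def _stage_logger(out_dir: str, stage: str) -> logging.Logger:
    os.makedirs(os.path.join(out_dir, "logs"), exist_ok=True)
    logger = logging.getLogger(f"alleleflow.run.{stage}")
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    handler = logging.FileHandler(os.path.join(out_dir, "logs", f"{stage}.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.propagate = False
    return logger


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured workflow; returns (and writes) the output manifest."""
    out_dir = config.out_dir
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"mode": config.mode, "seed": config.seed, "donors": {}}

    # ------------------------------------------------------------------ demux
    log = _stage_logger(out_dir, "demux")
    if config.multiplexed:
        try:
            tag_ref = {h.split()[0]: s for h, s in read_fasta(config.tags)}
            matrix = dmx.count_tags_from_files(
                config.r1, config.r2, tag_ref, config.barcode_spec
            )
            assignment = dmx.assign_tags(matrix, threshold=config.demux_threshold)
            split = dmx.split_fastq(
                config.r1, config.r2, assignment, config.barcode_spec,
                os.path.join(out_dir, "demux"),
            )
            assignment.to_csv(os.path.join(out_dir, "demux", "assignment.csv"), index=False)
            counts = assignment["status"].value_counts().to_dict()
            log.info("assignment summary: %s", counts)
            donor_inputs = {tag: paths for tag, paths in split["files"].items()}
        except Exception as exc:  # noqa: BLE001 - stage context is the point
            raise StageError("demux", exc) from exc
    else:
        log.info("demultiplexing skipped: input is not multiplexed")
        donor_inputs = {"donor": (config.r1, config.r2)}
    manifest["demux_skipped"] = not config.multiplexed

    class_map = config.class_map or DEFAULT_CLASS_MAP

    for donor, (r1, r2) in sorted(donor_inputs.items()):
        donor_dir = os.path.join(out_dir, donor)
        os.makedirs(donor_dir, exist_ok=True)

        # ----------------------------------------------------------- typing
        log = _stage_logger(out_dir, f"typing.{donor}")
        try:
            from ._fastq import read_fastq

            reads = [rec.sequence for rec in read_fastq(r2)]
            if config.mode == "wta":
                db = AlleleDatabase.from_fasta(config.allele_db)
                compat = build_compatibility(
                    [r for r in reads if len(r) >= config.k_typing],
                    db, k=config.k_typing,
                )
                log.info(
                    "compatibility: %d reads retained, %d dropped",
                    compat.matrix.shape[0], compat.n_dropped,
                )
                typing = em_select_alleles(
                    compat, homozygote_fraction=config.homozygote_fraction
                )
                resolver = db
            else:
                amp_ref = {h.split()[0]: s for h, s in read_fasta(config.amplicon_ref)}
                typing = amplicon_variant_typing(
                    reads, amp_ref,
                    min_minor_fraction=config.min_minor_fraction,
                    min_variant_reads=config.min_variant_reads,
                    k=config.k_amplicon,
                )
                resolver = None
            typed_fa = os.path.join(donor_dir, "typed_alleles.fa")
            records, gene_map = typing_to_fasta(typing, resolver, out_path=typed_fa)
            with open(os.path.join(donor_dir, "typing.json"), "w") as fh:
                json.dump(typing.to_dict(), fh, indent=2)
            log.info("typed alleles: %s", sorted(gene_map))
        except Exception as exc:
            raise StageError(f"typing.{donor}", exc) from exc

        # -------------------------------------------------------- reference
        log = _stage_logger(out_dir, f"buildref.{donor}")
        try:
            if config.mode == "wta":
                t2g = read_t2g(config.t2g) if config.t2g else {}
                base = config.base_cdna
            else:
                # amplicon runs quantify against the amplicon targets only
                t2g = {g: g for g in gene_map.values()}
                base = []
            immune = set(gene_map.values())
            ref = build_donor_reference(base, t2g, immune, records, gene_map)
            log.info(
                "reference: removed %d, appended %d, retained %d",
                ref.n_removed, ref.n_appended, ref.n_retained,
            )
            ref.to_fasta(os.path.join(donor_dir, "donor_reference.fa"))
            lookup = build_lookup(gene_map, class_map)
        except Exception as exc:
            raise StageError(f"buildref.{donor}", exc) from exc

        # ----------------------------------------------------------- quant
        log = _stage_logger(out_dir, f"quant.{donor}")
        try:
            base_counts, barcodes, base_ids, _ = quantify_run(
                r1, r2, ref, config.barcode_spec, k=config.k_quant
            )
            log.info("quantified %d barcodes x %d base features",
                     base_counts.shape[0], base_counts.shape[1])
        except Exception as exc:
            raise StageError(f"quant.{donor}", exc) from exc

        # ------------------------------------------------------------- qc
        log = _stage_logger(out_dir, f"qc.{donor}")
        try:
            exp = build_multilayer(base_counts, base_ids, lookup, cell_ids=barcodes)
            threshold: Optional[float] = None
            if config.knee == "auto":
                curve = qcmod.barcode_rank_inflection(exp.base_totals())
                threshold = curve.threshold_counts
                curve.to_frame().to_csv(
                    os.path.join(donor_dir, "knee_curve.tsv"), sep="\t", index=False
                )
            else:
                threshold = config.manual_knee_threshold()
            if threshold is not None:
                exp = qcmod.filter_cells(
                    exp, threshold, mito_max_fraction=config.mito_max_fraction
                )
            if exp.n_cells and (exp.base_totals() > 0).all():
                exp = qcmod.normalize_log(exp)
            report = qcmod.qc_report(exp)
            with open(os.path.join(donor_dir, "qc_report.json"), "w") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            paths = write_experiment(exp, donor_dir)
            log.info("retained %d cells", exp.n_cells)
        except Exception as exc:
            raise StageError(f"qc.{donor}", exc) from exc

        manifest["donors"][donor] = {
            "counts_matrix": paths["matrix"],
            "barcodes": paths["barcodes"],
            "features": paths["features"],
            "lookup": paths["lookup"],
            "typing": os.path.join(donor_dir, "typing.json"),
            "reference": os.path.join(donor_dir, "donor_reference.fa"),
        }

    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    manifest["manifest_path"] = manifest_path
    for donor_files in manifest["donors"].values():
        for path in donor_files.values():
            if not os.path.exists(path):
                raise RuntimeError(f"manifest references missing file: {path}")
    return manifest
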