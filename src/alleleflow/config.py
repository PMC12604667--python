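"""Run configuration: YAML parsing, validation and defaults."""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .demux import BarcodeSpec

MODES = ("wta", "amplicon")


@dataclass
class RunConfig:
    mode: str
    out_dir: str
    r1: str
    r2: str
    multiplexed: bool = False
    tags: Optional[str] = None
    base_cdna: Optional[str] = None
    t2g: Optional[str] = None
    allele_db: Optional[str] = None      # wta mode
    amplicon_ref: Optional[str] = None   # amplicon mode
    class_map: Optional[dict] = None
    barcode_spec: BarcodeSpec = field(default_factory=BarcodeSpec)
    demux_threshold: float = 0.75
    homozygote_fraction: float = 0.85
    min_minor_fraction: float = 0.25
    min_variant_reads: int = 10
    knee: str = "auto"                   # auto | none | manual:<N>
    mito_max_fraction: float = 0.2
    k_quant: int = 31
    k_typing: int = 31
    k_amplicon: int = 21
    seed: int = 0

    def manual_knee_threshold(self) -> Optional[float]:
        if self.knee.startswith("manual:"):
            return float(self.knee.split(":", 1)[1])
        return None


class ConfigError(ValueError):
    """Raised with the full list of validation problems."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


def validate_config(path_or_dict: str | dict) -> RunConfig:
    """Parse and validate a YAML config; all problems reported together."""
    if isinstance(path_or_dict, (str, os.PathLike)):
        with open(path_or_dict) as fh:
            try:
                raw = yaml.safe_load(fh)
            except yaml.YAMLError as exc:
                raise ConfigError([f"unparseable YAML: {exc}"]) from exc
    else:
        raw = dict(path_or_dict)
    if not isinstance(raw, dict):
        raise ConfigError(["config must be a YAML mapping"])

    errors: list[str] = []
    warnings: list[str] = []

    mode = raw.get("mode")
    if mode not in MODES:
        errors.append(f"mode must be one of {MODES}, got {mode!r}")
    for key in ("r1", "r2", "out_dir"):
        if not raw.get(key):
            errors.append(f"missing required field: {key}")

    multiplexed = bool(raw.get("multiplexed", False))
    if multiplexed and not raw.get("tags"):
        errors.append("multiplexed runs require a 'tags' FASTA path")
    if mode == "wta":
        if not raw.get("allele_db"):
            errors.append("wta mode requires 'allele_db'")
        if raw.get("amplicon_ref"):
            warnings.append("both allele_db and amplicon_ref given; mode=wta wins")
    if mode == "amplicon" and not raw.get("amplicon_ref"):
        errors.append("amplicon mode requires 'amplicon_ref'")
    if mode == "wta" and not raw.get("base_cdna"):
        errors.append("wta mode requires 'base_cdna'")

    thresholds = raw.get("thresholds", {}) or {}
    demux_threshold = float(thresholds.get("demux", 0.75))
    if not 0 < demux_threshold <= 1:
        errors.append("demux threshold must be in (0, 1]")
    homozygote_fraction = float(thresholds.get("homozygote_fraction", 0.85))
    if not 0.5 < homozygote_fraction <= 1:
        errors.append("homozygote_fraction must be in (0.5, 1]")
    min_minor_fraction = float(thresholds.get("min_minor_fraction", 0.25))
    if not 0 < min_minor_fraction <= 1:
        errors.append("min_minor_fraction must be in (0, 1]")
    mito_max = float(thresholds.get("mito_max", 0.2))
    if not 0 <= mito_max <= 1:
        errors.append("mito_max must be in [0, 1]")
    knee = str(thresholds.get("knee", "auto"))
    if knee not in ("auto", "none") and not knee.startswith("manual:"):
        errors.append("knee must be 'auto', 'none' or 'manual:<N>'")

    bc = raw.get("barcode", {}) or {}
    spec = BarcodeSpec(
        bc_start=int(bc.get("bc_start", 0)),
        bc_len=int(bc.get("bc_len", 16)),
        umi_start=int(bc.get("umi_start", bc.get("bc_start", 0) + bc.get("bc_len", 16))),
        umi_len=int(bc.get("umi_len", 12)),
    )
    if spec.bc_len <= 0 or spec.umi_len <= 0:
        errors.append("barcode and UMI lengths must be positive")

    k = raw.get("k", {}) or {}
    if errors:
        raise ConfigError(errors)
    cfg = RunConfig(
        mode=str(mode),
        out_dir=str(raw["out_dir"]),
        r1=str(raw["r1"]),
        r2=str(raw["r2"]),
        multiplexed=multiplexed,
        tags=raw.get("tags"),
        base_cdna=raw.get("base_cdna"),
        t2g=raw.get("t2g"),
        allele_db=raw.get("allele_db"),
        amplicon_ref=raw.get("amplicon_ref"),
        class_map=raw.get("class_map"),
        barcode_spec=spec,
        demux_threshold=demux_threshold,
        homozygote_fraction=homozygote_fraction,
        min_minor_fraction=min_minor_fraction,
        min_variant_reads=int(thresholds.get("min_variant_reads", 10)),
        knee=knee,
        mito_max_fraction=mito_max,
        k_quant=int(k.get("quant", 31)),
        k_typing=int(k.get("typing", 31)),
        k_amplicon=int(k.get("amplicon", 21)),
        seed=int(raw.get("seed", 0)),
    )
    cfg._warnings = warnings  # type: ignore[attr-defined]
    return cfg
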