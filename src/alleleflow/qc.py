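"""Empty-droplet filtering, layer-aware normalization and QC metrics.

Empty droplets are removed with the barcode-rank knee plot: barcodes are
ranked by total base-layer UMI count and the inflection point of the
log-log rank curve (the steepest descent to the right of the knee)
separates cell-containing droplets from ambient barcodes.

Normalization is layer-aware: the count matrix carries aggregate layers
that duplicate allele counts, so size factors are computed from the base
layer only — immune reads are never counted twice — and then applied to
every layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .layers import (
    LAYER_ALLELE,
    LAYER_CLASS,
    MultiLayerExperiment,
    build_multilayer,
)

log = logging.getLogger(__name__)


@dataclass
class BarcodeRankCurve:
    """Barcode-rank curve with detected knee and inflection positions."""

    order: np.ndarray          # barcode indices sorted by decreasing total
    totals: np.ndarray         # totals in that order (non-increasing)
    ranks: np.ndarray          # 1-based ranks
    knee_rank: int
    inflection_rank: int
    threshold_counts: float

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"rank": self.ranks, "total": self.totals})
        df["is_knee"] = df["rank"] == self.knee_rank
        df["is_inflection"] = df["rank"] == self.inflection_rank
        return df


def _running_median(y: np.ndarray, window: int = 5) -> np.ndarray:
    half = window // 2
    out = np.empty_like(y)
    for i in range(len(y)):
        lo = max(0, i - half)
        hi = min(len(y), i + half + 1)
        out[i] = np.median(y[lo : hi])
    return out


def barcode_rank_inflection(totals: Sequence[float]) -> BarcodeRankCurve:
    """Locate the knee-plot inflection point on per-barcode totals.

    On the log10(rank) vs log10(total) curve (one point per distinct total,
    at the mean rank of its ties), the curve is smoothed with a 5-point
    running median; the knee is the point of minimum signed curvature and
    the inflection the point of steepest (most negative) slope at or right
    of the knee.  Barcodes with total >= ``threshold_counts`` (the total at
    the inflection) are called cells.
    """
    totals = np.asarray(totals, dtype=float)
    if (totals > 0).sum() < 10:
        raise ValueError(
            "fewer than 10 barcodes with positive totals; knee detection is "
            "unreliable — supply a manual threshold"
        )
    order = np.argsort(-totals, kind="stable")
    sorted_totals = totals[order]
    pos = sorted_totals[sorted_totals > 0]
    ranks = np.arange(1, len(pos) + 1, dtype=float)

    # one point per distinct total, averaging the ranks of ties
    df = pd.DataFrame({"total": pos, "rank": ranks})
    pts = df.groupby("total", sort=False)["rank"].mean().reset_index()
    x = np.log10(pts["rank"].to_numpy())
    y = np.log10(pts["total"].to_numpy())
    if len(x) < 2:
        raise ValueError("all totals identical: no knee to locate")
    srt = np.argsort(x)
    x, y = x[srt], y[srt]
    ysm = _running_median(y, window=5)

    dy = np.gradient(ysm, x)
    d2y = np.gradient(dy, x)
    knee_i = int(np.argmin(d2y))
    infl_i = knee_i + int(np.argmin(dy[knee_i:]))
    threshold = float(10 ** y[infl_i])
    knee_rank = int(round(10 ** x[knee_i]))
    inflection_rank = int(round(10 ** x[infl_i]))
    return BarcodeRankCurve(
        order=order,
        totals=sorted_totals,
        ranks=np.arange(1, len(sorted_totals) + 1),
        knee_rank=knee_rank,
        inflection_rank=inflection_rank,
        threshold_counts=threshold,
    )


def filter_cells(
    exp: MultiLayerExperiment,
    threshold_counts: float,
    mito_max_fraction: float = 0.2,
    mito_prefix: str = "MT-",
) -> MultiLayerExperiment:
    """Retain cells passing the count threshold and mitochondrial filter.

    Cells with base-layer total >= ``threshold_counts`` and mitochondrial
    fraction <= ``mito_max_fraction`` are kept; aggregates are recomputed on
    the retained submatrix (never stale).
    """
    if not 0 <= mito_max_fraction <= 1:
        raise ValueError("mito_max_fraction must be in [0, 1]")
    totals = exp.base_totals()
    mito = mito_fraction(exp, mito_prefix)
    keep = (totals >= threshold_counts) & (mito <= mito_max_fraction)
    n_low = int((totals < threshold_counts).sum())
    n_mito = int(((totals >= threshold_counts) & (mito > mito_max_fraction)).sum())
    log.info("filter_cells: removed %d low-count, %d high-mito; retained %d/%d",
             n_low, n_mito, int(keep.sum()), exp.n_cells)
    if not keep.any():
        raise ValueError("cell filtering removed every cell")
    base_mask = exp.base_mask()
    base = exp.counts[:, base_mask][keep]
    base_ids = [f for f, m in zip(exp.feature_ids, base_mask) if m]
    cell_ids = [c for c, k in zip(exp.cell_ids, keep) if k]
    meta = (
        exp.cell_metadata.iloc[np.where(keep)[0]]
        if len(exp.cell_metadata) == exp.n_cells
        else exp.cell_metadata
    )
    return build_multilayer(
        base, base_ids, exp.lookup, cell_ids=cell_ids, cell_metadata=meta
    )


def mito_fraction(exp: MultiLayerExperiment, mito_prefix: str = "MT-") -> np.ndarray:
    """Per-cell fraction of base-layer counts on mitochondrial features."""
    base_mask = exp.base_mask()
    mito_mask = base_mask & np.array(
        [f.startswith(mito_prefix) for f in exp.feature_ids]
    )
    totals = exp.base_totals()
    mito = np.asarray(exp.counts[:, mito_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(totals > 0, mito / np.maximum(totals, 1e-300), 0.0)
    return frac


def normalize_log(exp: MultiLayerExperiment) -> MultiLayerExperiment:
    """Median-ratio size factors from the base layer, log2(x/s + 1) everywhere.

    s_c = (base-layer total of cell c) / (median base-layer total); the
    normalized value log2(count / s_c + 1) is computed for every layer,
    base and aggregate alike, with the same base-derived s_c — aggregate
    layers duplicate immune counts and must not influence the factors.
    """
    if exp.n_cells < 1:
        raise ValueError("no cells to normalize")
    totals = exp.base_totals()
    if (totals <= 0).any():
        raise ValueError(
            "cells with zero base-layer counts present; filter them before normalizing"
        )
    size_factors = totals / float(np.median(totals))
    norm = sp.csr_matrix(exp.counts, dtype=float, copy=True)
    inv = 1.0 / size_factors
    scale = sp.diags(inv)
    norm = scale @ norm
    norm.data = np.log2(norm.data + 1.0)
    exp.size_factors = size_factors
    exp.normalized = sp.csr_matrix(norm)
    return exp


@dataclass
class QCReport:
    per_cell: pd.DataFrame
    median_total_counts: float
    median_hla_counts: float
    class_ii_apc_ratio: Optional[float] = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "median_total_counts": self.median_total_counts,
            "median_hla_counts": self.median_hla_counts,
            "class_ii_apc_ratio": self.class_ii_apc_ratio,
            "warnings": self.warnings,
        }


def qc_report(
    exp: MultiLayerExperiment,
    apc_barcodes: Optional[Sequence[str]] = None,
    mito_prefix: str = "MT-",
    class_ii_label: str = "HLA_class_II",
) -> QCReport:
    """Per-cell QC metrics plus dataset-level medians.

    Reports total base counts, mitochondrial fraction and total HLA-allele
    counts per cell; dataset medians of these; and, when an
    antigen-presenting-cell barcode set is supplied, the ratio of mean
    class II aggregate expression in APCs vs all other cells (an internal
    sanity signal — reported, not enforced).
    """
    warnings: list[str] = []
    totals = exp.base_totals()
    mito = mito_fraction(exp, mito_prefix)
    allele_mask = exp.layer_mask({LAYER_ALLELE})
    if allele_mask.any():
        hla = np.asarray(exp.counts[:, allele_mask].sum(axis=1)).ravel()
    else:
        hla = np.zeros(exp.n_cells)
        warnings.append("no allele features present; HLA metrics reported as 0")
        log.warning("no allele features present; HLA metrics reported as 0")
    per_cell = pd.DataFrame(
        {
            "barcode": exp.cell_ids,
            "total_base_counts": totals,
            "mito_fraction": mito,
            "total_hla_counts": hla,
        }
    )
    ratio = None
    if apc_barcodes is not None:
        class_mask = exp.layer_mask({LAYER_CLASS}) & np.array(
            [f == class_ii_label for f in exp.feature_ids]
        )
        if class_mask.any():
            apc_set = set(apc_barcodes)
            is_apc = np.array([c in apc_set for c in exp.cell_ids])
            if is_apc.any() and (~is_apc).any():
                vals = np.asarray(exp.counts[:, class_mask].sum(axis=1)).ravel()
                other_mean = vals[~is_apc].mean()
                ratio = float(vals[is_apc].mean() / other_mean) if other_mean > 0 else float("inf")
        else:
            warnings.append(f"class aggregate {class_ii_label} not present; APC check skipped")
    return QCReport(
        per_cell=per_cell,
        median_total_counts=float(np.median(totals)) if len(totals) else 0.0,
        median_hla_counts=float(np.median(hla)) if len(hla) else 0.0,
        class_ii_apc_ratio=ratio,
        warnings=warnings,
    )


def plot_knee(curve: BarcodeRankCurve, path: str) -> None:
    """Save a log-log barcode-rank plot with knee and inflection marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    pos = curve.totals > 0
    ax.plot(curve.ranks[pos], curve.totals[pos], lw=1)
    ax.axvline(curve.knee_rank, color="grey", ls="--", label="knee")
    ax.axvline(curve.inflection_rank, color="red", ls="--", label="inflection")
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("barcode rank")
    ax.set_ylabel("total UMI counts")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
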