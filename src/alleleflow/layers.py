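"""Multilayer count container for allele-specific single-cell quantification.

The quantifier emits a *base layer* of features: conventional gene-level
counts for nonimmune genes plus allele-level counts for the typed immune
alleles.  A lookup table maps every allele feature to its gene and functional
class (e.g. HLA class I / class II).  On top of the base layer this module
materializes two aggregate layers:

1. ``gene_aggregate`` — per-gene sums over the alleles of that gene;
2. ``class_aggregate`` — per-class sums over the gene aggregates.

Nonimmune genes never contribute to an aggregate; a functional class of
``"none"`` marks immune features outside any class grouping and likewise
contributes to no class aggregate.  Aggregates are stored, not lazily
computed, so conservation can be asserted on the object itself, and any
operation that subsets cells rebuilds them from the base layer.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

LAYER_NONIMMUNE = "nonimmune_gene"
LAYER_ALLELE = "allele"
LAYER_GENE = "gene_aggregate"
LAYER_CLASS = "class_aggregate"
VALID_LAYERS = frozenset({LAYER_NONIMMUNE, LAYER_ALLELE, LAYER_GENE, LAYER_CLASS})
BASE_LAYERS = frozenset({LAYER_NONIMMUNE, LAYER_ALLELE})

#: functional-class value marking "belongs to no class grouping"
NO_CLASS = "none"


class AlleleLookupTable:
    """Rows of (feature_id, gene_id, functional_class) driving aggregation.

    feature_id values are unique allele-level feature names; gene_id is the
    gene each allele belongs to; functional_class groups genes (class value
    ``"none"`` opts a feature out of the class layer).
    """

    COLUMNS = ("feature_id", "gene_id", "functional_class")

    def __init__(self, df: pd.DataFrame):
        df = df.loc[:, list(self.COLUMNS)].astype(str).reset_index(drop=True)
        if df["feature_id"].duplicated().any():
            dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
            raise ValueError(f"duplicate feature_id in lookup: {dups}")
        if (df["gene_id"].str.len() == 0).any():
            raise ValueError("lookup rows must have non-empty gene_id")
        feat = set(df["feature_id"])
        clash = feat & (set(df["gene_id"]) | set(df["functional_class"]))
        if clash:
            raise ValueError(
                f"feature ids collide with gene/class labels: {sorted(clash)}"
            )
        self.df = df

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, str]]
    ) -> "AlleleLookupTable":
        return cls(pd.DataFrame(list(records), columns=list(cls.COLUMNS)))

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "AlleleLookupTable":
        return cls(pd.read_csv(path, dtype=str))

    def to_csv(self, path: str | os.PathLike) -> None:
        self.df.to_csv(path, index=False)

    @property
    def feature_ids(self) -> list[str]:
        return self.df["feature_id"].tolist()

    def gene_of(self) -> dict[str, str]:
        return dict(zip(self.df["feature_id"], self.df["gene_id"]))

    def class_of_gene(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for g, c in zip(self.df["gene_id"], self.df["functional_class"]):
            if g in out and out[g] != c:
                raise ValueError(f"gene {g} mapped to multiple functional classes")
            out[g] = c
        return out

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, AlleleLookupTable) and self.df.equals(other.df)


@dataclass
class MultiLayerExperiment:
    """cells x features sparse counts whose features carry a layer label."""

    counts: sp.csr_matrix
    cell_ids: list[str]
    feature_ids: list[str]
    feature_layer: np.ndarray  # dtype=object/str, one label per feature
    lookup: AlleleLookupTable
    cell_metadata: pd.DataFrame = field(default_factory=pd.DataFrame)
    normalized: Optional[sp.csr_matrix] = None
    size_factors: Optional[np.ndarray] = None

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def layer_mask(self, layers: Iterable[str]) -> np.ndarray:
        layers = set(layers)
        unknown = layers - VALID_LAYERS
        if unknown:
            raise ValueError(f"unknown layer label(s): {sorted(unknown)}")
        return np.isin(self.feature_layer, sorted(layers))

    def base_mask(self) -> np.ndarray:
        return self.layer_mask(BASE_LAYERS)

    def base_totals(self) -> np.ndarray:
        """Per-cell total counts over the base layer only."""
        mask = self.base_mask()
        return np.asarray(self.counts[:, mask].sum(axis=1)).ravel()


def _aggregate_columns(
    base: sp.csr_matrix,
    base_ids: Sequence[str],
    groups: Mapping[str, list[str]],
) -> tuple[sp.csr_matrix, list[str]]:
    """Sum base columns into one column per group key (keys sorted)."""
    col_of = {f: i for i, f in enumerate(base_ids)}
    keys = sorted(groups)
    if not keys:
        return sp.csr_matrix((base.shape[0], 0), dtype=base.dtype), []
    cols = []
    for key in keys:
        idx = [col_of[f] for f in groups[key]]
        cols.append(base[:, idx].sum(axis=1))
    agg = sp.csr_matrix(np.hstack([np.asarray(c) for c in cols]))
    return agg, keys


def build_multilayer(
    base_counts: sp.spmatrix,
    base_feature_ids: Sequence[str],
    lookup: AlleleLookupTable,
    class_map: Optional[Mapping[str, str]] = None,
    cell_ids: Optional[Sequence[str]] = None,
    cell_metadata: Optional[pd.DataFrame] = None,
) -> MultiLayerExperiment:
    """Build the multilayer object from base-layer counts and a lookup table.

    Features named in the lookup are labelled ``allele``; all others
    ``nonimmune_gene``.  One ``gene_aggregate`` column is appended per
    distinct gene_id and one ``class_aggregate`` column per distinct
    functional class (class ``"none"`` excluded), both sorted
    lexicographically.  ``class_map`` optionally overrides the lookup's
    gene -> class assignment.

    Raises ``ValueError`` if lookup features are missing from the base
    matrix, if base feature ids are duplicated, or if an aggregate name
    collides with a base feature id.
    """
    base_feature_ids = [str(f) for f in base_feature_ids]
    if len(set(base_feature_ids)) != len(base_feature_ids):
        seen: set[str] = set()
        dups = {f for f in base_feature_ids if f in seen or seen.add(f)}
        raise ValueError(f"duplicate base feature ids: {sorted(dups)}")
    base = sp.csr_matrix(base_counts)
    if base.nnz and base.min() < 0:
        raise ValueError("counts must be non-negative")
    if base.shape[1] != len(base_feature_ids):
        raise ValueError("base_feature_ids length does not match matrix")

    base_set = set(base_feature_ids)
    missing = [f for f in lookup.feature_ids if f not in base_set]
    if missing:
        raise ValueError(f"allele feature(s) missing from base counts: {missing}")

    gene_of = lookup.gene_of()
    cls_of = dict(lookup.class_of_gene())
    if class_map is not None:
        cls_of.update({str(g): str(c) for g, c in class_map.items()})

    allele_set = set(lookup.feature_ids)
    layers = np.array(
        [LAYER_ALLELE if f in allele_set else LAYER_NONIMMUNE for f in base_feature_ids],
        dtype=object,
    )

    gene_groups: dict[str, list[str]] = {}
    for f in base_feature_ids:
        if f in allele_set:
            gene_groups.setdefault(gene_of[f], []).append(f)
    gene_agg, gene_ids = _aggregate_columns(base, base_feature_ids, gene_groups)

    class_groups: dict[str, list[str]] = {}
    for g in gene_ids:
        c = cls_of.get(g, NO_CLASS)
        if c != NO_CLASS:
            class_groups.setdefault(c, []).append(g)
    class_agg, class_ids = _aggregate_columns(gene_agg, gene_ids, class_groups)

    collide = (set(gene_ids) | set(class_ids)) & base_set
    if collide:
        raise ValueError(f"aggregate names collide with base features: {sorted(collide)}")

    counts = sp.hstack([base, gene_agg, class_agg], format="csr")
    feature_ids = base_feature_ids + gene_ids + class_ids
    feature_layer = np.concatenate(
        [layers, np.full(len(gene_ids), LAYER_GENE, dtype=object),
         np.full(len(class_ids), LAYER_CLASS, dtype=object)]
    )
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(base.shape[0])]
    cell_ids = [str(c) for c in cell_ids]
    if len(set(cell_ids)) != len(cell_ids):
        raise ValueError("cell_ids must be unique")
    meta = cell_metadata.copy() if cell_metadata is not None else pd.DataFrame(index=cell_ids)
    meta.index = pd.Index(cell_ids, name="barcode")
    meta["total_base_counts"] = np.asarray(base.sum(axis=1)).ravel()
    return MultiLayerExperiment(
        counts=counts,
        cell_ids=list(cell_ids),
        feature_ids=feature_ids,
        feature_layer=feature_layer,
        lookup=lookup,
        cell_metadata=meta,
    )


def get_layer(
    exp: MultiLayerExperiment, layer_selector: Iterable[str]
) -> tuple[sp.csr_matrix, list[str]]:
    """Return (matrix, feature ids) for the features in the selected layers."""
    selector = set(layer_selector)
    if not selector:
        raise ValueError("layer selector must be non-empty")
    mask = exp.layer_mask(selector)
    ids = [f for f, m in zip(exp.feature_ids, mask) if m]
    return exp.counts[:, mask], ids


def write_experiment(exp: MultiLayerExperiment, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write counts (MatrixMarket), barcodes, features-with-layer and lookup.

    Layout matches the four downstream-analysis files: ``matrix.mtx``,
    ``barcodes.txt``, ``features.tsv`` (feature_id <tab> layer) and
    ``lookup.csv``; cell metadata goes to ``cell_metadata.csv``.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "matrix": os.path.join(out_dir, "matrix.mtx"),
        "barcodes": os.path.join(out_dir, "barcodes.txt"),
        "features": os.path.join(out_dir, "features.tsv"),
        "lookup": os.path.join(out_dir, "lookup.csv"),
        "cell_metadata": os.path.join(out_dir, "cell_metadata.csv"),
    }
    scipy.io.mmwrite(paths["matrix"], sp.coo_matrix(exp.counts))
    with open(paths["barcodes"], "w") as fh:
        fh.writelines(b + "\n" for b in exp.cell_ids)
    with open(paths["features"], "w") as fh:
        fh.write("feature_id\tlayer\n")
        for f, l in zip(exp.feature_ids, exp.feature_layer):
            fh.write(f"{f}\t{l}\n")
    exp.lookup.to_csv(paths["lookup"])
    exp.cell_metadata.to_csv(paths["cell_metadata"])
    return paths


def read_experiment(out_dir: str | os.PathLike) -> MultiLayerExperiment:
    """Read back an experiment written by :func:`write_experiment`."""
    out_dir = str(out_dir)
    counts = sp.csr_matrix(scipy.io.mmread(os.path.join(out_dir, "matrix.mtx")))
    with open(os.path.join(out_dir, "barcodes.txt")) as fh:
        cell_ids = [line.strip() for line in fh if line.strip()]
    feats = pd.read_csv(os.path.join(out_dir, "features.tsv"), sep="\t", dtype=str)
    lookup = AlleleLookupTable.from_csv(os.path.join(out_dir, "lookup.csv"))
    meta_path = os.path.join(out_dir, "cell_metadata.csv")
    meta = pd.read_csv(meta_path, index_col=0) if os.path.exists(meta_path) else pd.DataFrame(index=cell_ids)
    # mmread of an empty matrix can come back with wrong cell count
    if counts.shape[0] != len(cell_ids):
        counts = sp.csr_matrix((len(cell_ids), len(feats)))
    return MultiLayerExperiment(
        counts=counts,
        cell_ids=cell_ids,
        feature_ids=feats["feature_id"].tolist(),
        feature_layer=feats["layer"].to_numpy(dtype=object),
        lookup=lookup,
        cell_metadata=meta,
    )
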