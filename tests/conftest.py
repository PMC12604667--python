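import numpy as np
import pytest
import scipy.sparse as sp

from alleleflow.layers import AlleleLookupTable, build_multilayer


@pytest.fixture
def hla_lookup() -> AlleleLookupTable:
    return AlleleLookupTable.from_records(
        [
            ("A*01:01", "HLA-A", "HLA_class_I"),
            ("A*24:02", "HLA-A", "HLA_class_I"),
            ("B*35:02", "HLA-B", "HLA_class_I"),
            ("DRA*01:01", "HLA-DRA", "HLA_class_II"),
        ]
    )


@pytest.fixture
def small_experiment(hla_lookup):
    base = sp.csr_matrix(
        np.array(
            [
                [3, 2, 1, 4, 10],
                [0, 5, 2, 0, 20],
                [1, 1, 1, 1, 5],
            ]
        )
    )
    ids = ["A*01:01", "A*24:02", "B*35:02", "DRA*01:01", "GAPDH"]
    return build_multilayer(base, ids, hla_lookup, cell_ids=["c1", "c2", "c3"])


def random_base_and_lookup(rng: np.random.Generator, n_cells: int, n_features: int):
    """Random sparse base matrix with a random allele->gene->class lookup."""
    dense = rng.integers(0, 5, size=(n_cells, n_features)) * (
        rng.random((n_cells, n_features)) < 0.4
    )
    n_alleles = rng.integers(0, n_features + 1)
    ids = [f"AL{i}" if i < n_alleles else f"G{i}" for i in range(n_features)]
    rows = []
    for i in range(n_alleles):
        gene = f"gene{rng.integers(1, 4)}"
        cls = ["classA", "classB", "none"][rng.integers(3)]
        rows.append((ids[i], gene, cls))
    # one class per gene: last assignment wins, so rebuild consistently
    gene_cls = {g: c for _, g, c in rows}
    rows = [(f, g, gene_cls[g]) for f, g, _ in rows]
    return sp.csr_matrix(dense), ids, AlleleLookupTable.from_records(rows)
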