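import itertools

import numpy as np
import pytest

from alleleflow.demux import BarcodeSpec
from alleleflow.quantify import (
    canonical,
    collapse_umis,
    em_distribute,
    index_reference,
    pseudoalign,
    quantify_run,
    revcomp,
    _em_theta,
)
from alleleflow.reference import (
    ORIGIN_ALLELE,
    ORIGIN_BASE,
    DonorReference,
    ReferenceRecord,
)
from alleleflow.simulate import make_allele_set, make_barcodes, simulate_cell_reads

SPEC = BarcodeSpec()


class TestIndex:
    def test_kmer_count_single_transcript(self):
        seq = "".join(np.random.default_rng(1).choice(list("ACGT"), 100))
        idx = index_reference([("t0", seq)], k=31)
        # L - k + 1 k-mers, all mapping to transcript 0 (minus canonical merges)
        assert sum(len(v) for v in idx.kmer_map.values()) == 70
        assert all(v == frozenset({0}) for v in idx.kmer_map.values())

    def test_identical_transcripts_share_all_kmers(self):
        seq = "".join(np.random.default_rng(2).choice(list("ACGT"), 80))
        idx = index_reference([("a", seq), ("b", seq)], k=31)
        assert all(v == frozenset({0, 1}) for v in idx.kmer_map.values())

    def test_short_transcript_warns_and_empty_reference_errors(self, caplog):
        idx = index_reference([("s", "ACGT" * 7), ("t", "ACGT" * 20)], k=31)
        assert any("shorter than k" in m for m in caplog.messages)
        assert 0 not in {t for v in idx.kmer_map.values() for t in v}
        with pytest.raises(ValueError, match="empty"):
            index_reference([], k=31)

    def test_canonical_strandness(self):
        assert canonical("AAAC") == canonical(revcomp("AAAC"))


@pytest.fixture(scope="module")
def two_transcripts():
    rng = np.random.default_rng(9)
    shared = "".join(rng.choice(list("ACGT"), 60))
    u0 = "".join(rng.choice(list("ACGT"), 60))
    u1 = "".join(rng.choice(list("ACGT"), 60))
    t0 = u0 + shared
    t1 = u1 + shared
    return index_reference([("t0", t0), ("t1", t1)], k=31), t0, t1


class TestPseudoalign:
    def test_unique_region(self, two_transcripts):
        idx, t0, _ = two_transcripts
        assert pseudoalign(t0[:50], idx) == frozenset({0})

    def test_shared_region(self, two_transcripts):
        idx, t0, _ = two_transcripts
        assert pseudoalign(t0[65:115], idx) == frozenset({0, 1})

    def test_reverse_complement_read(self, two_transcripts):
        idx, t0, _ = two_transcripts
        assert pseudoalign(revcomp(t0[:50]), idx) == frozenset({0})

    def test_chimeric_read_rejected(self, two_transcripts):
        idx, t0, t1 = two_transcripts
        chimera = t0[:31] + t1[25:56]  # unique halves -> empty intersection
        assert pseudoalign(chimera, idx) is None

    def test_foreign_read_none(self, two_transcripts):
        idx, _, _ = two_transcripts
        assert pseudoalign("A" * 50, idx) is None


class TestCollapseUmis:
    def test_duplicate_intersection(self):
        out = collapse_umis(
            [("b", "u", frozenset({0, 1})), ("b", "u", frozenset({0}))]
        )
        assert out == {"b": {(0,): 1}}

    def test_distinct_umis_counted(self):
        out = collapse_umis(
            [("b", "u1", frozenset({0})), ("b", "u2", frozenset({0}))]
        )
        assert out == {"b": {(0,): 2}}

    def test_disjoint_duplicates_lexicographic_tiebreak(self):
        out = collapse_umis(
            [("b", "u", frozenset({1})), ("b", "u", frozenset({0}))]
        )
        assert out == {"b": {(0,): 1}}

    def test_majority_wins_over_lexicographic(self):
        out = collapse_umis(
            [
                ("b", "u", frozenset({1})),
                ("b", "u", frozenset({1})),
                ("b", "u", frozenset({0})),
            ]
        )
        # intersection empty; {1} is the most frequent set among duplicates
        assert out == {"b": {(1,): 1}}

    def test_total_equals_distinct_pairs(self):
        rng = np.random.default_rng(17)
        records = []
        for _ in range(500):
            bc = f"b{rng.integers(3)}"
            umi = f"u{rng.integers(40)}"
            ec = frozenset(rng.choice(4, size=rng.integers(1, 4), replace=False).tolist())
            records.append((bc, umi, ec))
        out = collapse_umis(records)
        distinct = {(b, u) for b, u, _ in records}
        for bc in out:
            expected = sum(1 for (b, _u) in distinct if b == bc)
            assert sum(out[bc].values()) == expected


def grid_mle_loglik(ec_sets, counts, n_transcripts, step=1e-3):
    """Brute-force MLE of the multinomial mixture over a simplex grid."""
    m = np.zeros((len(ec_sets), n_transcripts))
    for i, ec in enumerate(ec_sets):
        m[i, list(ec)] = 1.0
    counts = np.asarray(counts, dtype=float)
    ticks = np.arange(0.0, 1.0 + step / 2, step)
    best_ll, best_theta = -np.inf, None
    if n_transcripts == 2:
        thetas = np.column_stack([ticks, 1 - ticks])
    else:
        grid = [(a, b, 1 - a - b) for a, b in itertools.product(ticks, ticks) if a + b <= 1 + 1e-12]
        thetas = np.array(grid)
    ll = np.full(len(thetas), -np.inf)
    probs = thetas @ m.T  # (n_grid, n_ecs)
    ok = (probs > 0).all(axis=1)
    ll[ok] = (np.log(probs[ok]) * counts).sum(axis=1)
    j = int(np.argmax(ll))
    return float(ll[j]), thetas[j]


class TestEMDistribute:
    def test_unique_evidence_dominates(self):
        ecs = {"c": {(0,): 10, (0, 1): 10}}
        mat, _ = em_distribute(ecs, 2)
        arr = mat.toarray()[0]
        assert arr[0] == pytest.approx(20, abs=0.01)
        assert arr[1] == pytest.approx(0, abs=0.01)

    def test_pure_ambiguity_splits_evenly(self):
        mat, _ = em_distribute({"c": {(0, 1): 10}}, 2)
        np.testing.assert_allclose(mat.toarray()[0], [5, 5])

    def test_unambiguous_exact(self):
        mat, _ = em_distribute({"c": {(0,): 6, (1,): 4}}, 2)
        np.testing.assert_allclose(mat.toarray()[0], [6, 4])

    def test_out_of_range_index_errors(self):
        with pytest.raises(ValueError, match="out of range"):
            em_distribute({"c": {(5,): 1}}, 2)

    def test_per_cell_conservation(self):
        rng = np.random.default_rng(23)
        ecs = {}
        for c in range(8):
            cell = {}
            for _ in range(rng.integers(1, 6)):
                ec = tuple(sorted(rng.choice(5, size=rng.integers(1, 4), replace=False)))
                cell[ec] = cell.get(ec, 0) + int(rng.integers(1, 30))
            ecs[f"c{c}"] = cell
        for mode in ({"pool": "all_cells"}, {"pool": "per_cell"}, {"uniform_split": True}):
            mat, barcodes = em_distribute(ecs, 5, **mode)
            for bc, row in zip(barcodes, mat.toarray()):
                assert abs(row.sum() - sum(ecs[bc].values())) < 1e-9

    @pytest.mark.parametrize(
        "ec_sets,counts,n",
        [
            ([(0,), (0, 1)], [10, 10], 2),
            ([(0, 1)], [10], 2),
            ([(0,), (1,)], [6, 4], 2),
            ([(0,), (0, 1), (1, 2)], [5, 10, 8], 3),
            ([(0, 1, 2)], [9], 3),
            ([(0, 1), (1, 2), (0, 2)], [3, 6, 9], 3),
            ([(0,), (1, 2)], [7, 7], 3),
        ],
    )
    def test_em_matches_grid_mle(self, ec_sets, counts, n):
        """EM fixed point attains the grid-search maximum likelihood."""
        theta, trace = _em_theta(
            list(ec_sets), np.array(counts, float), n, tol=1e-12, max_iter=5000
        )
        ll_grid, theta_grid = grid_mle_loglik(ec_sets, counts, n)
        m = np.zeros((len(ec_sets), n))
        for i, ec in enumerate(ec_sets):
            m[i, list(ec)] = 1.0
        ll_em = float(np.dot(counts, np.log(m @ theta)))
        assert ll_em >= ll_grid - 1e-4
        assert (np.diff(trace) >= -1e-9).all()


@pytest.fixture(scope="module")
def simulated_run(tmp_path_factory):
    tmp = tmp_path_factory.mktemp("quant")
    alleles, _ = make_allele_set("HLA-A", 1000, 2, 5, seed=41)
    a1, a2 = sorted(alleles)
    rng = np.random.default_rng(42)
    nonimmune = "".join(rng.choice(list("ACGT"), 1000))
    tx = {"GAPDH": nonimmune, a1: alleles[a1], a2: alleles[a2]}
    barcodes = make_barcodes(5, 16, rng)
    props = {bc: {"GAPDH": 0.6, a1: 0.2, a2: 0.2} for bc in barcodes}
    r1, r2 = str(tmp / "r1.fq.gz"), str(tmp / "r2.fq.gz")
    simulate_cell_reads(tx, props, 200, 90, 0.001, seed=43, r1_path=r1, r2_path=r2)
    ref = DonorReference(
        records=[
            ReferenceRecord("GAPDH-tx1", nonimmune, ORIGIN_BASE, "GAPDH"),
            ReferenceRecord(a1, alleles[a1], ORIGIN_ALLELE, "HLA-A"),
            ReferenceRecord(a2, alleles[a2], ORIGIN_ALLELE, "HLA-A"),
        ]
    )
    return r1, r2, ref, (a1, a2)


class TestQuantifyRun:
    def test_base_features_and_proportions(self, simulated_run):
        r1, r2, ref, (a1, a2) = simulated_run
        counts, barcodes, feats, table = quantify_run(r1, r2, ref)
        assert feats == ["GAPDH", a1, a2]
        arr = counts.toarray()
        pooled = arr.sum(axis=0) / arr.sum()
        # 3x binomial SE on the pooled proportion
        n = arr.sum()
        for p_hat, p_true in zip(pooled, [0.6, 0.2, 0.2]):
            se = np.sqrt(p_true * (1 - p_true) / n)
            assert abs(p_hat - p_true) <= 3 * se

    def test_per_cell_totals_conserved(self, simulated_run):
        r1, r2, ref, _ = simulated_run
        counts, barcodes, _, _ = quantify_run(r1, r2, ref)
        totals = counts.toarray().sum(axis=1)
        # 200 UMIs per cell simulated; UMI collisions can merge a couple
        assert (np.abs(totals - 200) <= 3).all()
        assert (np.abs(totals - np.round(totals)) < 1e-9).all()

    def test_zero_reads_degenerate(self, tmp_path, simulated_run):
        _, _, ref, _ = simulated_run
        from alleleflow._fastq import write_fastq

        r1, r2 = str(tmp_path / "e1.fq"), str(tmp_path / "e2.fq")
        write_fastq(r1, [])
        write_fastq(r2, [])
        counts, barcodes, feats, _ = quantify_run(r1, r2, ref)
        assert counts.shape == (0, 3)
        assert barcodes == []

    def test_identical_alleles_split_evenly_and_sum_matches_single(self, tmp_path):
        seq = "".join(np.random.default_rng(51).choice(list("ACGT"), 800))
        rng = np.random.default_rng(52)
        barcodes = make_barcodes(4, 16, rng)
        props = {bc: {"X*01:01": 1.0} for bc in barcodes}
        r1, r2 = str(tmp_path / "r1.fq.gz"), str(tmp_path / "r2.fq.gz")
        simulate_cell_reads(
            {"X*01:01": seq}, props, 150, 90, 0.0, seed=53, r1_path=r1, r2_path=r2
        )
        dup_ref = DonorReference(
            records=[
                ReferenceRecord("X*01:01", seq, ORIGIN_ALLELE, "HLA-X"),
                ReferenceRecord("X*01:02", seq, ORIGIN_ALLELE, "HLA-X"),
            ]
        )
        single_ref = DonorReference(
            records=[ReferenceRecord("X*01:01", seq, ORIGIN_ALLELE, "HLA-X")]
        )
        dup, bcs_dup, _, _ = quantify_run(r1, r2, dup_ref)
        single, bcs_single, _, _ = quantify_run(r1, r2, single_ref)
        d, s = dup.toarray(), single.toarray()
        order = np.argsort(bcs_dup)
        order_s = np.argsort(bcs_single)
        np.testing.assert_allclose(d[order, 0], d[order, 1])  # 50/50 split
        np.testing.assert_allclose(
            d[order].sum(axis=1), s[order_s, 0], rtol=1e-6
        )
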