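# Methods

This note documents the models and procedures `alleleflow` implements, the
parameters that matter, the numerical choices behind them, and what the
synthetic data generators do and do not emulate.

## Problem setting

A donor's HLA genes are usually heterozygous, and the two allele cDNA
sequences of a gene typically differ at only a handful of positions over
1–3 kb. Quantifying them separately in scRNA-seq therefore requires (i)
knowing which alleles the donor carries, (ii) a reference that contains
exactly those allele sequences instead of a generic gene model, and (iii)
a counting scheme that keeps, rather than discards, reads compatible with
both alleles. The pipeline stages below implement these three requirements,
plus the demultiplexing and QC machinery around them.

## Sample-tag demultiplexing

Tag evidence is counted by direct sequence matching: a read pair
contributes to count n(b, t) when the R1 barcode (coordinates from the
barcode spec, 0-based half-open; defaults 16 nt barcode + 12 nt UMI) is b
and R2 contains tag t's sequence. Matching is exact substring search by
default; a fixed R2 offset and a mismatch tolerance (0 or 1 substitutions)
are configuration knobs, because tag-read structure differs across kits and
we deliberately do not model any vendor's proprietary layout.

The dominant-tag rule assigns barcode b to tag t when
n(b,t) / Σ n(b,·) ≥ 0.75. The bound is inclusive — a 3:1 read split is
assigned, not a multiplet — and 0.75 is the workflow default, configurable
in (0, 1]. Barcodes whose top fraction falls below the threshold are
multiplets and their reads are dropped. Barcodes with *zero* tag reads get
a separate `undetermined` status rather than being folded into multiplets:
the multiplet concept only makes sense for barcodes with evidence, and
keeping the two apart makes the diagnostics honest. For thresholds ≤ 0.5 an
argmax tie can clear the threshold; ties are resolved to multiplet
(ambiguity is treated as ambiguity, never broken arbitrarily in favor of a
donor).

## WTA allele typing

### Compatibility model

Candidate alleles come from an allele-database FASTA with IMGT-style
headers (`A*24:02:01:01` → gene HLA-A). Read–allele compatibility uses an
intersection rule over *informative* k-mers (k = 31, the standard
pseudoalignment length): read r is compatible with allele a iff every
k-mer of r that occurs anywhere in the database also occurs in a. K-mers
absent from the whole database are skipped — they are almost always
sequencing errors, and skipping them keeps error-bearing reads usable —
while a k-mer that *is* in the database but missing from allele a is
positive evidence against a. Reads with no database k-mer, or whose
informative k-mers jointly rule out every allele, are dropped before EM.

### Per-gene EM

Per gene, allele abundances θ are estimated by multinomial-mixture EM over
the boolean compatibility matrix: uniform initialization, E-step assigning
each read fractionally to its compatible alleles proportional to θ, M-step
renormalizing expected counts; convergence at max |Δθ| < 1e-6 or 1000
iterations. The log-likelihood Σ_r log Σ_{a∈C_r} θ_a is non-decreasing
across iterations by EM construction, and the test suite asserts the trace.
A read whose compatible alleles span several genes enters each such gene's
EM with its set restricted to that gene's alleles; this symmetric treatment
avoids having to adjudicate cross-gene reads, which are rare at realistic
divergences.

The call is the top allele alone when its θ ≥ `homozygote_fraction`
(default 0.85), else the top two. The 0.85 default reflects that a true
heterozygote with codominant expression sits near θ ≈ 0.5/0.5, a true
homozygote near 1.0, and ambiguous-read leakage rarely moves a homozygote's
top fraction below ~0.9 at ≥10 substitutions/kb divergence; the knob is
exposed because this margin shrinks with divergence. Ties in θ break by
allele-name lexicographic order, so results are deterministic given input
order; two sequence-identical candidates split θ evenly and are reported as
the top two in name order.

## Amplicon allele typing

Amplicon sequencing observes only the covered slice of each target, so
variants cannot be resolved to registry alleles; they are reported under
arbitrary identifiers (`GENE-AV-1`, `GENE-AV-2`) that carry no nomenclature
meaning. Reads are assigned to their best amplicon by k-mer containment
(k = 21 — amplicons and their reads are shorter than whole transcripts),
located on the reference by the first exactly-matching seed k-mer
(ungapped; the substitution-only error model makes this adequate), and
grouped by mismatch signature: the set of (position, base) substitutions
over the read's covered positions. Reads with identical covered-position
base calls share a group. Groups with fewer than `min_variant_reads`
(default 10) reads are discarded as sequencing-error singletons. The top
group by read count becomes AV-1 (consensus = reference with the group's
substitutions applied); the runner-up becomes AV-2 iff its count is at
least `min_minor_fraction` (default 0.25) of the top count. Both thresholds
are explicit knobs: the one-vs-two decision has no canonical value, and
0.25 tolerates moderate allelic imbalance while rejecting error-driven
minor groups. A consequence of signature grouping worth knowing: a read
from the minor variant that does not cover the variant position is
indistinguishable from the reference group and is counted there.

## Donor reference and lookup table

The donor reference is the base transcriptome with *all* transcripts of
immune-listed genes deleted and the typed allele sequences appended. All
isoforms are removed, not just a canonical one — leaving any would let
reads bleed between a gene-level transcript and its own alleles. An immune
gene with no typed alleles is removed and loudly logged as unquantifiable;
retaining it would mix gene-level and allele-level features for the same
locus. A typed allele whose gene is not in the immune list is an error, as
the gene would be represented twice. Transcript→gene mapping comes from a
2-column TSV (a minimal GTF reader extracting gene_id/transcript_id is
provided as a convenience).

The lookup table has one row per typed allele (feature_id, gene_id,
functional_class), ordered by (gene, allele). The shipped class map sends
HLA-A/B/C to `HLA_class_I` and HLA-DRA/DRB1/DQA1/DQB1/DPA1/DPB1 to
`HLA_class_II`; genes outside the map get class `"none"` and are excluded
from the class layer. Feature names are validated against gene and class
labels to prevent cross-layer name collisions.

## Quantification

The k-mer index stores canonical k-mers (lexicographic minimum of a k-mer
and its reverse complement; k odd so no k-mer is its own complement),
making pseudoalignment strand-agnostic — library strandedness varies across
chemistries. A read's equivalence class is the intersection of the
transcript sets of its indexed k-mers; index-absent k-mers are skipped
(error tolerance) but an empty intersection rejects the read (a read
contradicting every transcript is noise or chimeric, and keeping it would
blur allele discrimination).

UMI collapse is by exact (barcode, UMI) match — no Hamming-1 merging, a
documented simplification that slightly overcounts molecules at real-world
sequencing error rates. Duplicates collapse to the intersection of their
classes when non-empty, else to the most frequent class (ties to the
lexicographically smallest set), so the per-barcode total equals the number
of distinct retained molecules.

Class counts are distributed over transcripts by EM on
L(θ) = Π_e (Σ_{t∈e} θ_t)^{n_e} with uniform initialization,
tolerance 1e-8, ≤1000 iterations. θ is estimated on the counts pooled over
all cells and then applied per cell (default `pool=all_cells`): individual
cells contribute a handful of molecules per immune gene, far too few for a
stable per-cell mixture estimate, while the pooled estimate mirrors
bulk-style EM; `per_cell` mode is retained as an option, as is a uniform
split (`uniform_split=True`) that mimics the naive multimapping treatment.
Per-cell distribution renormalizes θ within each class's transcript set, so
each cell's total expected count equals its retained UMI count to floating
point (asserted at 1e-9). Transcript-level expected counts of nonimmune
transcripts are summed into genes, giving a base feature set of nonimmune
genes plus alleles.

## Multilayer count structure

The base layer (nonimmune genes + alleles) is extended with one
`gene_aggregate` column per lookup gene (sum of its alleles) and one
`class_aggregate` column per functional class (sum of its gene aggregates),
appended after the base features in lexicographic order. Aggregates are
materialized, not lazy: conservation is then a testable invariant of the
stored object, and every cell-subsetting operation rebuilds them from the
base layer so they can never go stale. Nonimmune genes belong to no
aggregate; the data gives no basis for assigning them a functional class.
Aggregate names are the bare gene/class labels, with the collision
invariant enforced at construction so that selection by name is
unambiguous. On-disk layout is MatrixMarket counts + barcodes text +
features TSV with a layer column + lookup CSV — the four files downstream
analysis consumes — and write/read round-trips exactly.

## Empty-droplet filtering

On the log10(rank)–log10(total) barcode curve (one point per distinct
total, at the mean rank of its ties), totals are smoothed with a 5-point
running median; the knee is the point of minimum signed curvature (second
derivative) and the inflection the steepest descent (most negative first
derivative) at or right of the knee. Cells are barcodes with total ≥ the
total at the inflection. This is our own deterministic fixing of the
"inflection of the knee plot" concept — the notion is standard but no
single algorithm is; the definition here reproduces the expected behavior
on two-population barcode models (recall ≥ 99%, ambient leak-through ≤ 1%
over seeded replicates, asserted in the acceptance suite). Degenerate
inputs: fewer than 10 positive barcodes raises with advice to set a manual
threshold; perfectly flat totals raise (no knee exists). Mitochondrial
filtering removes cells with mito fraction > 0.2 (prefix `MT-`,
configurable).

## Layer-aware normalization

Size factors are median ratios of *base-layer* totals:
s_c = total_c / median(total). Aggregate layers duplicate every immune
count and must not influence the factors — this is asserted as a bit-level
invariance property under arbitrary mutation of aggregate columns. The
normalized value is log2(count / s_c + 1) for every layer using the
base-derived s_c. Order of operations is pinned: aggregates are normalized
from their *count* sums, i.e. the normalized gene value is
log2((Σ allele counts)/s_c + 1), which is *not* the sum of normalized
allele values; a test asserts exactly this to prevent a silent change.
Median scaling with log2(x+1) is the simplest factor model consistent with
layer-aware normalization; nothing downstream depends on the specific
pseudo-count.

## QC report

Per cell: total base counts, mitochondrial fraction, total HLA-allele
counts. Per dataset: medians of these (allele-level quantification is only
trustworthy when the median HLA count per cell is reasonably high — the
report surfaces the number, the user judges the cutoff). As an internal
biological control, when the user supplies a set of antigen-presenting-cell
barcodes the report includes the ratio of mean HLA class II aggregate
expression in that set versus all other cells; APCs should be enriched.
The ratio is reported, never enforced.

## Synthetic data

The generators are pure functions of (parameters, seed) and emit truth
manifests next to every FASTQ, so any stage can be scored without
re-deriving truth.

* `make_allele_set` draws a uniform-ACGT base sequence and places each
  allele's substitutions at positions disjoint across alleles, so pairwise
  divergence is exactly 2× the per-allele substitution count — the control
  variable for all specificity experiments. An option confines differences
  to the first 80% of the sequence, emulating poly-A-proximal similarity,
  which is where 3'-chemistry coverage concentrates and where allele
  discrimination genuinely suffers.
* `simulate_cell_reads` draws per-cell UMI counts per feature from a
  multinomial at the requested proportions, one read per UMI from a uniform
  start position, with independent per-base substitution errors (default
  experiments use 0.1%). R1 is barcode + UMI; quality strings are a
  constant Q40.
* `simulate_tag_reads` gives each singlet its true tag with probability
  1 − contamination and a uniform other tag otherwise; doublets draw 50/50
  from two tags.
* `simulate_ambient_barcodes` draws totals from negative binomials with
  var = mean + 0.5·mean² (cells: mean 5000; ambient: mean 10). The
  dispersion 0.5 is a declared constant, not fitted to any dataset.

What the generators do **not** emulate — and hence what passing tests do
not establish about real data: indels and structural variation (the error
model is substitution-only, and the seed-and-locate steps assume it),
3'-coverage bias (read starts are uniform unless the poly-A option is
used), realistic transcriptome-wide expression profiles, barcode sequencing
errors (no whitelist correction exists), PCR amplification bias, and
quality-score structure. Results on real libraries will degrade with all of
these, most of all with indel-bearing platforms.

## Problem sizes and determinism

Acceptance experiments run at desk scale, chosen to make the statistics
decisive while keeping the whole suite interactive: typing recovery uses 20
replicate donors × 1000 reads against 10 candidate alleles; ratio recovery
uses 10000 pooled UMIs for the point estimate and 8 replicates × 5000 UMIs
per divergence level for the error curve; knee evaluation uses 500 cells vs
20000 ambient barcodes × 10 seeds; the end-to-end check runs 2 donors × 12
cells twice. Divergence-monotonicity experiments reuse the same seed list
across divergence levels (common random numbers), so the similarity effect
is not confounded with independent sampling noise. Every stochastic step
takes an explicit seed; EM itself is deterministic, and two pipeline runs
with the same config and seed produce byte-identical count matrices.

## Known limitations

* Typing assumes the true alleles are in the candidate database; novel
  alleles are typed as their nearest database neighbor.
* No G/P nomenclature groups, no class II DRB copy-number handling, no
  intron-aware genomic typing.
* UMI collapse without Hamming-1 merging overcounts molecules slightly.
* The knee detector needs a clear two-population structure; shallow or
  multi-modal curves deserve a manual threshold.
* Amplicon variant grouping is signature-exact: at high error rates true
  variant groups fragment, and `min_variant_reads` trades sensitivity
  against error robustness.
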