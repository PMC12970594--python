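# Methods

This note documents the models, conventions and numerical choices behind
`utrext`, and what the synthetic benchmark does and does not demonstrate.

## Coordinate and format conventions

All coordinates are 1-based closed internally, the native GTF/GFF
convention; BED/broadPeak/bedGraph input is converted from 0-based
half-open at the boundary and converted back on output. GTF and GFF3 are
distinguished by the attribute syntax of the first data row
(`key "value";` vs `key=value`); GFF2 files parse through the GTF path.
In GTF, `gene_id`/`transcript_id` are treated as *grouping keys*: gene and
even transcript rows may be missing and are synthesized. In GFF3,
`Parent` is a *reference*: an exon pointing at a nonexistent transcript is
a hard error listing the dangling IDs. Output carries only
`gene_id`/`transcript_id` (GTF) or `ID`/`Parent` (GFF3) and only
gene/transcript/exon rows — CDS and UTR rows are consumed internally (for
benchmark truncation) but not re-emitted, because UMI demultiplexers use
exon geometry only.

## Annotation repair

* Missing genes: a transcript without a gene row gets one gene per
  declared parent ID (grouping transcripts that share it); a transcript
  with no parent at all gets `<transcript_id>_gene`. The synthesized gene
  spans the union of its transcripts and carries only the minimal
  attribute set — we deliberately do not copy transcript attributes onto
  it, since nothing downstream reads them.
* ID collisions are resolved with priority gene > transcript > exon, then
  file order; later claimants receive `_1`, `_2`, … suffixes and children
  follow their parent's rename through object identity. The common
  one-transcript-per-gene pathology (transcript reusing the gene's ID)
  therefore renames the transcript, never the gene. Repair is idempotent.
* Transcripts with no exon rows receive a single exon spanning the
  transcript, so exon-overlap counters see the gene at all.
* "Longest isoform" is the transcript with maximal **summed exon length**
  (mRNA-length semantics), not genomic span; ties break to the
  lexicographically smallest transcript ID so reruns are stable.
* Genes on strand `.` are passed through untouched and excluded from
  extension and orphan logic — without a strand, 3′ is undefined.

Annotation statistics (used for run-time defaults) are computed on the
repaired, one-isoform, pre-extension annotation: introns are the positive
gaps between consecutive exons of a transcript, and all percentiles —
including the intron-length p75 and the median gene/transcript length —
use linear interpolation between order statistics, pinned so the values
are reproducible bit for bit. An annotation with no introns falls back to
p75 = 1000 bp (configurable) with a warning.

## Peak evidence

Three routes yield interchangeable `Peak` objects:

1. **Built-in caller** (default, dependency-free). Per strand, the
   background rate λ is the genome-wide mean depth; bases whose depth
   reaches the smallest *d* with `P(Poisson(λ) ≥ d) ≤ q` (q = 0.01) are
   thresholded, maximal runs separated by < `extsize` (100 bp) are merged,
   and merged runs shorter than `min_length` (30 bp) are discarded. This
   is a documented simplification of a broad-mode caller with a global
   rather than dynamic background; its contract is frozen by an exhaustive
   run-scan oracle in the test suite.
2. **External MACS2**, when the binary is present: strand-split BAMs and
   `callpeak -f BAM --keep-dup 20 -q 0.01 --shift 1 --extsize 100 --broad
   --nomodel --min-length 30` per strand.
3. **Pre-called broadPeak/BED files**, with the strand taken from column 6
   or forced per file for strand-split runs.

Peak coverage is always recomputed from the coverage track — the score
columns of peak files are never trusted. Coverage itself adds one unit of
depth per primary alignment block (spliced gaps contribute nothing) on the
strand of the read's orientation; a `flip_strand` option covers libraries
whose read is antisense to the transcript. Subsampling keeps each read
independently with probability `n_target / n_total` under the given seed.

Classification uses **gene spans** (≥ 1 bp same-strand overlap ⇒ genic):
compared to exon-level classification this errs toward genic, i.e. toward
*fewer* false intergenic peaks, which is the conservative direction for
extension; exon-level classification is available behind a flag. The
genic-coverage percentile is pooled over both strands. "Exceeding the
percentile" is read strictly: an intergenic peak exactly at the threshold
is dropped. With zero genic peaks the threshold is undefined; all
intergenic peaks are kept and a prominent warning is logged rather than
silently discarding evidence.

## Extension

A peak is assignable to gene G iff it is on G's chromosome and strand,
lies strictly downstream of G's 3′ end in the strand sense, *starts*
within `-m` of that end, and no same-strand gene sits between (the
nearest-eligible-gene rule makes the obstruction check implicit: an
intervening gene is by construction nearer). Each peak goes to at most
one gene, preventing double counting in the UMI matrix. The new 3′ end is
the far edge of the most distal assigned peak, clamped to
`old 3′ + m` and to one bp short of the nearest same-strand downstream
gene start (computed on pre-extension coordinates, so results are
independent of processing order); a peak that is only partially within
range is clamped at the cap rather than discarded. Gene, retained
transcript and terminal exon move identically — extending the terminal
exon rather than adding a new one keeps the 3′ signal contiguous for
exon-overlap counting. Opposite-strand genes neither obstruct nor cap an
extension, and a supporting peak may overlap an opposite-strand gene:
3′-biased evidence is strand-resolved, so cross-strand signal is not
evidence against the extension.

## Orphan genes

Orphan clustering runs *after* extension, on the filtered intergenic
peaks left unassigned, and re-checks collisions against the extended
annotation (a cluster landing inside a freshly extended gene is dropped
with a warning). Chaining is single-linkage within a chromosome/strand:
gap ≤ `orphan_maxdist` (auto = intron-length p75) joins peaks; clusters
with span > `orphan_maxsize` (auto = median gene length) are removed;
`--nomerge` makes every peak its own cluster. Each emitted cluster
becomes one gene + one transcript with **one exon per member peak** —
merging the exons into one interval would let unrelated intergenic signal
between the peaks inflate the count, and separate features per peak is
exactly the double-counting the clustering exists to prevent. IDs are
`orphan_<n>` in genomic order with source column `utrext_orphan`, so
orphan features are easy to grep out of the final annotation.

## Overlap resolution

Containment removal drops every gene fully contained in a same-strand
gene (identical spans: the lexicographically larger ID goes, with a
warning). Clipping then walks each chromosome/strand left-to-right in the
strand sense, keeping a frontier at the most advanced 3′ end seen; a gene
starting behind the frontier has its 5′ boundary moved to one bp past it,
exons fully inside the clipped region deleted and a straddling exon
truncated. A clip that would consume a gene entirely is skipped and
logged as a conflict. For chains of three or more mutually overlapping
genes the outcome is order-dependent (upstream genes win in turn); this
is documented rather than resolved, since no ordering is canonical.
Clipping never moves a 3′ end and extension never moves a 5′ end — the
test suite asserts both jointly. Clipping runs before peak
classification so genic/intergenic labels reflect the resolved models.

## Benchmark harness

`truncate_utrs` pulls every gene/transcript/terminal-exon 3′ boundary
back to the coding 3′ end taken from CDS rows (or an explicit per-gene
table); non-coding genes are left untouched and listed.
`compare_three_prime_ends` reports the signed, strand-aware distance per
shared gene (positive = candidate past the original) with median |d|,
fraction exact, and fractions within 10/100/1000 bp.
`cluster_expression_correlation` aggregates each cell cluster to its mean
count per gene — the simplest aggregation consistent with "expression per
cell type" — and computes Pearson r over the genes present in both
matrices; clusters under 3 cells are flagged. Matrices are exchanged as
MatrixMarket triplets with feature/barcode lists. Quantification itself
(STARsolo, CellRanger) is out of scope; the harness consumes their
outputs or synthetic matrices.

## Synthetic worlds

The generator packs non-overlapping two-exon genes (~50 % per strand)
along each chromosome, with uniform gene lengths (1500–3000 bp), 3′ UTRs
(50–400 bp) inside the terminal exon, introns (100–400 bp) and intergenic
gaps (1000–3000 bp) — sizes in the range of compact invertebrate genomes,
where 3′ mis-annotation matters most. CDS rows cover the coding part, so
the truncated copy (UTRs removed) is exactly recoverable and
`truncate_utrs(original)` reproduces it — a generator/harness
cross-check. Evidence is an idealized 3′-biased profile: a genic plateau
over the coding 3′ window and a stronger plateau (2×) over the true UTR,
so the UTR peak clears the 25th-percentile genic threshold strictly;
noise blocks (depth 2 ≪ threshold) land in intergenic gaps; planted
orphan genes are two-block groups placed > 5 kb beyond the last gene of a
chromosome, outside extension range. A configurable fraction of genes
carries planted file-level pathologies (missing gene rows, duplicated
IDs, contained genes, 5′/3′ overlaps), materialized by the world's own
GTF writer and tagged in the truth table.

Coverage is emitted as plateaus rather than simulated read stacks: every
pipeline decision depends only on depth and geometry, so plateaus exercise
the same code paths while staying bit-for-bit reproducible (a small
sorted BAM with the same geometry is available for the alignment-ingestion
path). Consequently, passing tests demonstrate the *logic* — exact end
recovery, strict thresholding, cap enforcement, clustering — but not
robustness to ragged real-world coverage, soft-clipping, antisense
bleed-through, or internal priming; on real data the recovered end is the
evidence boundary, which need not be the annotated end to the base.

## Problem sizes and determinism

Tests and the acceptance script use genomes of 12–200 genes across 2–4
chromosomes and worlds of ≥ 1000 randomized genes for cap/overlap
invariants — sizes at which every property is checked exhaustively while
the whole suite runs in seconds. All randomness flows through explicit
seeds (`numpy.random.default_rng`); identical inputs and seed give
byte-identical outputs, which the suite verifies by hashing.
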