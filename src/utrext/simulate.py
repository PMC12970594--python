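"""Hermetic synthetic worlds: annotations with known 3' ends plus evidence.

The generator builds a toy multi-chromosome genome annotation in which
every gene has a known "true" 3' end and a known 3' UTR, together with a
truncated copy (the UTRs removed — emulating the incomplete gene models
typical of non-model genomes) and strand-specific coverage with a strong
3'-biased plateau over each gene's terminal window *including* the UTR.
Extension pipelines run on the truncated copy must therefore recover the
true ends from the evidence alone.  Low-coverage noise peaks and
unannotated "orphan gene" signal blocks can be injected, all recorded in a
truth table.

Coverage is emitted as idealized plateaus rather than read stacks: every
decision the pipeline makes depends only on depth and geometry, so
plateaus exercise the same code paths as realistic stacks while staying
bit-for-bit reproducible.  Evidence is emitted as bedGraph + broadPeak by
default; :func:`make_alignments` additionally materializes the same
geometry as a small sorted BAM for the alignment-ingestion path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation_io import EXON, GENE, OTHER, TRANSCRIPT, Feature, GenomeAnnotation
from .evidence import CoverageTrack, Peak, attach_coverage, write_broadpeak

logger = logging.getLogger(__name__)

PATHOLOGY_TYPES = ("missing_gene_row", "duplicate_id", "contained_gene", "overlap_5prime")


@dataclass
class GenomeWorld:
    original: GenomeAnnotation
    truncated: GenomeAnnotation
    truth: pd.DataFrame  # per gene: spans, true 3' end, UTR length, pathology tag

    def write_gtf(self, path, which: str = "original", with_pathologies: bool = True) -> None:
        """Write one copy as GTF, materializing the planted file-level
        defects: ``missing_gene_row`` genes lose their gene row and
        ``duplicate_id`` transcripts are written with ``transcript_id``
        equal to their ``gene_id``.  With ``with_pathologies=False`` the
        output is a clean, well-formed file."""
        ann = {"original": self.original, "truncated": self.truncated}[which]
        patho = dict(zip(self.truth.gene_id, self.truth.pathology))
        with open(path, "w") as fh:
            for gene in sorted(ann.genes(), key=lambda g: (g.chrom, g.start, g.feature_id)):
                gid = gene.feature_id
                p = patho.get(gid, "") if with_pathologies else ""
                if p != "missing_gene_row":
                    fh.write(_gtf_row(gene, f'gene_id "{gid}";'))
                for tx in sorted(ann.transcripts_of(gid), key=lambda t: t.start):
                    tid = gid if p == "duplicate_id" else tx.feature_id
                    attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
                    fh.write(_gtf_row(tx, attrs))
                    for child in sorted(ann.children_of(tx.feature_id), key=lambda c: (c.start, c.ftype)):
                        fh.write(_gtf_row(child, attrs))


def _gtf_row(f: Feature, attrs: str) -> str:
    return "\t".join(
        [f.chrom, f.source or ".", f.ftype or f.kind, str(f.start), str(f.end),
         ".", f.strand, ".", attrs]
    ) + "\n"


@dataclass
class EvidenceWorld:
    track: CoverageTrack
    peaks: list[Peak]
    orphan_truth: pd.DataFrame
    noise_truth: pd.DataFrame

    def peaks_for_strand(self, strand: str) -> list[Peak]:
        return [p for p in self.peaks if p.strand == strand]

    def write(self, outdir) -> dict[str, Path]:
        """Write bedGraph coverage and broadPeak files (a combined stranded
        file plus per-strand files with '.' in the strand column, as a
        strand-split peak caller would produce)."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "coverage_plus": outdir / "coverage_plus.bedgraph",
            "coverage_minus": outdir / "coverage_minus.bedgraph",
            "peaks": outdir / "peaks.broadPeak",
            "peaks_plus": outdir / "peaks_plus.broadPeak",
            "peaks_minus": outdir / "peaks_minus.broadPeak",
        }
        self.track.write_bedgraph(paths["coverage_plus"], "+")
        self.track.write_bedgraph(paths["coverage_minus"], "-")
        write_broadpeak(self.peaks, paths["peaks"])
        for strand, key in (("+", "peaks_plus"), ("-", "peaks_minus")):
            with open(paths[key], "w") as fh:
                for p in self.peaks_for_strand(strand):
                    fh.write(
                        f"{p.chrom}\t{p.start - 1}\t{p.end}\t{p.name}\t0\t.\t"
                        f"{p.norm_coverage:.4f}\t-1\t-1\n"
                    )
        return paths


def make_genome(
    n_chroms: int = 2,
    n_genes: int = 20,
    gene_length_dist: tuple[int, int] = (1500, 3000),
    utr_length_dist: tuple[int, int] = (50, 400),
    intergenic_dist: tuple[int, int] = (1000, 3000),
    exon1_length_dist: tuple[int, int] = (150, 400),
    intron_length_dist: tuple[int, int] = (100, 400),
    pathology_fraction: float = 0.0,
    chrom_length: int | None = None,
    seed: int = 0,
) -> GenomeWorld:
    """Build a deterministic toy genome with known 3' ends.

    Genes are packed non-overlappingly along each chromosome, ~50% per
    strand, each with two exons, one intron, and a 3' UTR inside the
    terminal exon; CDS rows cover the coding part so the truncated copy is
    exactly recoverable.  ``pathology_fraction`` of genes get a planted
    defect (cycling: missing gene row, transcript reusing the gene ID, a
    contained gene, a 5'/3' overlapping neighbour), tagged in the truth
    table.  All distributions are uniform over (min, max) bounds.
    """
    rng = np.random.default_rng(seed)
    gmin, gmax = gene_length_dist
    umin, umax = utr_length_dist
    if gmin < exon1_length_dist[1] + intron_length_dist[1] + umax + 150:
        raise ValueError(
            "gene_length_dist too small for the requested exon/intron/UTR bounds"
        )

    n_path = int(round(pathology_fraction * n_genes))
    path_idx = sorted(rng.choice(n_genes, size=n_path, replace=False)) if n_path else []
    pathology = {int(i): PATHOLOGY_TYPES[k % len(PATHOLOGY_TYPES)] for k, i in enumerate(path_idx)}

    original = GenomeAnnotation(dialect="gtf")
    truncated = GenomeAnnotation(dialect="gtf")
    truth_rows: list[dict] = []

    def draw(lo: int, hi: int) -> int:
        return int(rng.integers(lo, hi + 1))

    per_chrom = [n_genes // n_chroms + (1 if c < n_genes % n_chroms else 0) for c in range(n_chroms)]
    idx = 0
    for c, count in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        cursor = 0
        force_overlap_with_prev = False
        prev_end = None
        for gi in range(count):
            g = draw(gmin, gmax)
            u = draw(umin, umax)
            e1 = draw(*exon1_length_dist)
            il = draw(*intron_length_dist)
            strand = "+" if rng.random() < 0.5 else "-"
            patho = pathology.get(idx, "")
            if force_overlap_with_prev:
                strand = "+"
                s = prev_end - 100 + 1  # 100 bp 5' overlap into the upstream 3' end
                force_overlap_with_prev = False
            else:
                gap = draw(*intergenic_dist)
                s = cursor + gap + 1
            e = s + g - 1
            if chrom_length is not None and e > chrom_length:
                raise ValueError(
                    f"infeasible packing: gene {idx} ends at {e} > chromosome length {chrom_length}"
                )
            if patho == "overlap_5prime" and gi + 1 < count:
                strand = "+"
                force_overlap_with_prev = True
            _build_gene(
                original, truncated, truth_rows,
                gene_idx=idx, chrom=chrom, start=s, end=e, strand=strand,
                utr=u, exon1=e1, intron=il, patho=patho,
            )
            prev_end = e
            cursor = max(cursor, e)
            idx += 1
    truth = pd.DataFrame(
        truth_rows,
        columns=["gene_id", "chrom", "strand", "start", "end", "true_3prime",
                 "coding_end", "utr_length", "pathology", "extendable"],
    )
    return GenomeWorld(original=original, truncated=truncated, truth=truth)


def _build_gene(original, truncated, truth_rows, *, gene_idx, chrom, start, end,
                strand, utr, exon1, intron, patho) -> None:
    gid = f"g{gene_idx:04d}"
    tid = f"{gid}.t"  # file-level ID pathologies are applied by write_gtf
    g = end - start + 1
    if strand == "+":
        ex1 = (start, start + exon1 - 1)
        ex2 = (start + exon1 + intron, end)
        coding_end = end - utr
        cds = [(ex1[0], ex1[1]), (ex2[0], coding_end)]
        true3 = end
        t_span = (start, coding_end)
        t_ex2 = (ex2[0], coding_end)
        exons, t_exons = [ex1, ex2], [ex1, t_ex2]
    else:
        term_len = g - exon1 - intron
        ex_term = (start, start + term_len - 1)
        ex1_r = (end - exon1 + 1, end)
        coding_end = start + utr
        cds = [(coding_end, ex_term[1]), (ex1_r[0], ex1_r[1])]
        true3 = start
        t_span = (coding_end, end)
        t_exterm = (coding_end, ex_term[1])
        exons, t_exons = [ex_term, ex1_r], [t_exterm, ex1_r]

    for ann, span, exs, with_cds in (
        (original, (start, end), exons, True),
        (truncated, t_span, t_exons, True),  # CDS unchanged by truncation
    ):
        ann.add(Feature(gid, GENE, chrom, span[0], span[1], strand, ftype="gene"))
        ann.add(
            Feature(tid, TRANSCRIPT, chrom, span[0], span[1], strand,
                    parent_id=gid, ftype="transcript")
        )
        for k, (es, ee) in enumerate(sorted(exs), start=1):
            ann.add(Feature(f"{tid}.exon{k}", EXON, chrom, es, ee, strand,
                            parent_id=tid, ftype="exon"))
        if with_cds:
            for k, (cs, ce) in enumerate(sorted(cds), start=1):
                ann.add(Feature(f"{tid}.cds{k}", OTHER, chrom, cs, ce, strand,
                                parent_id=tid, ftype="CDS"))
    truth_rows.append(
        {"gene_id": gid, "chrom": chrom, "strand": strand, "start": start, "end": end,
         "true_3prime": true3, "coding_end": coding_end, "utr_length": utr,
         "pathology": patho, "extendable": utr > 0}
    )

    if patho == "contained_gene":
        # a small same-strand gene buried in the coding-side half (present
        # in both copies; removed by containment resolution)
        if strand == "+":
            ispan = (start + 10, start + 209)
        else:
            ispan = (end - 209, end - 10)
        inner = f"{gid}_inner"
        for ann in (original, truncated):
            ann.add(Feature(inner, GENE, chrom, ispan[0], ispan[1], strand, ftype="gene"))
            ann.add(Feature(f"{inner}.t", TRANSCRIPT, chrom, ispan[0], ispan[1], strand,
                            parent_id=inner, ftype="transcript"))
            ann.add(Feature(f"{inner}.t.exon1", EXON, chrom, ispan[0], ispan[1], strand,
                            parent_id=f"{inner}.t", ftype="exon"))
        truth_rows.append(
            {"gene_id": inner, "chrom": chrom, "strand": strand,
             "start": ispan[0], "end": ispan[1],
             "true_3prime": ispan[1] if strand == "+" else ispan[0],
             "coding_end": ispan[1] if strand == "+" else ispan[0],
             "utr_length": 0, "pathology": "contained_inner", "extendable": False}
        )


# ---------------------------------------------------------------------------
# evidence
# ---------------------------------------------------------------------------


def make_evidence(
    original: GenomeAnnotation,
    truncated: GenomeAnnotation,
    signal_depth: float = 50.0,
    utr_depth: float | None = None,
    noise_peaks: int = 0,
    noise_depth: float = 2.0,
    orphan_genes: int = 0,
    orphan_block_length: int = 200,
    orphan_block_gap: int = 150,
    orphan_offset: int = 7000,
    orphan_spacing: int = 2500,
    genic_window: int = 150,
    seed: int = 0,
) -> EvidenceWorld:
    """3'-biased coverage and pre-called peaks for a synthetic world.

    Each gene shared by the original and truncated annotations gets a
    genic plateau of ``signal_depth`` over its coding 3' window and a
    stronger plateau of ``utr_depth`` (default 2 x signal) over the true
    UTR — intergenic relative to the truncated models, so extension is
    required to capture it.  ``noise_peaks`` sub-threshold blocks of depth
    ``noise_depth`` land at random intergenic spots, and ``orphan_genes``
    two-block signal groups are planted beyond extension range on each
    chromosome tail.  Everything is recorded in truth tables.
    """
    rng = np.random.default_rng(seed)
    utr_depth = 2.0 * signal_depth if utr_depth is None else utr_depth

    orig_genes = {g.feature_id: g for g in original.genes() if g.strand in "+-"}
    trunc_genes = {g.feature_id: g for g in truncated.genes() if g.strand in "+-"}
    shared = sorted(set(orig_genes) & set(trunc_genes))

    blocks: list[tuple[str, str, int, int, float, str]] = []  # chrom,strand,s,e,depth,name
    for gid in shared:
        og, tg = orig_genes[gid], trunc_genes[gid]
        c = tg.three_prime()
        if og.strand == "+":
            gs = max(tg.start, c - genic_window + 1)
            blocks.append((og.chrom, "+", gs, c, signal_depth, f"sig_{gid}"))
            if og.end > c:
                blocks.append((og.chrom, "+", c + 1, og.end, utr_depth, f"utr_{gid}"))
        else:
            ge = min(tg.end, c + genic_window - 1)
            blocks.append((og.chrom, "-", c, ge, signal_depth, f"sig_{gid}"))
            if og.start < c:
                blocks.append((og.chrom, "-", og.start, c - 1, utr_depth, f"utr_{gid}"))

    # intergenic gaps of the original annotation (margin keeps noise clear
    # of UTR signal and of internal-caller merge range)
    spans: dict[str, list[tuple[int, int]]] = {}
    for g in original.genes():
        spans.setdefault(g.chrom, []).append((g.start, g.end))
    gaps: list[tuple[str, int, int]] = []
    for chrom, ivals in spans.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            lo, hi = e1 + 150, s2 - 150
            if hi - lo + 1 >= 120:
                gaps.append((chrom, lo, hi))
    if noise_peaks and not gaps:
        raise ValueError("no intergenic gap wide enough to place noise peaks")
    noise_rows = []
    for i in range(noise_peaks):
        chrom, lo, hi = gaps[i % len(gaps)]
        s = int(rng.integers(lo, hi - 80 + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        blocks.append((chrom, strand, s, s + 79, noise_depth, f"noise_{i}"))
        noise_rows.append({"name": f"noise_{i}", "chrom": chrom, "strand": strand,
                           "start": s, "end": s + 79})

    chrom_max = {g.chrom: 0 for g in original.genes()}
    for g in original.genes():
        chrom_max[g.chrom] = max(chrom_max[g.chrom], g.end)
    chroms = sorted(chrom_max)
    cursors = {c: chrom_max[c] + orphan_offset for c in chroms}
    orphan_rows = []
    for j in range(orphan_genes):
        chrom = chroms[j % len(chroms)]
        p = cursors[chrom]
        strand = "+" if j % 2 == 0 else "-"
        b1 = (p, p + orphan_block_length - 1)
        b2s = p + orphan_block_length + orphan_block_gap
        b2 = (b2s, b2s + orphan_block_length - 1)
        for k, (bs, be) in enumerate((b1, b2), start=1):
            blocks.append((chrom, strand, bs, be, utr_depth, f"orphanblk_{j}_{k}"))
        cursors[chrom] = b2[1] + orphan_spacing
        orphan_rows.append({"orphan_id": f"planted_{j}", "chrom": chrom, "strand": strand,
                            "span_start": b1[0], "span_end": b2[1], "n_blocks": 2})

    lengths = {c: m + orphan_offset + 2000 for c, m in chrom_max.items()}
    for chrom, strand, s, e, d, name in blocks:
        lengths[chrom] = max(lengths.get(chrom, 0), e + 2000)
    track = CoverageTrack(lengths)
    peaks: list[Peak] = []
    for chrom, strand, s, e, d, name in blocks:
        track.add_block(chrom, strand, s, e, d)
        peaks.append(Peak(chrom=chrom, start=s, end=e, strand=strand, name=name))
    attach_coverage(peaks, track)
    return EvidenceWorld(
        track=track,
        peaks=peaks,
        orphan_truth=pd.DataFrame(
            orphan_rows, columns=["orphan_id", "chrom", "strand", "span_start", "span_end", "n_blocks"]
        ),
        noise_truth=pd.DataFrame(
            noise_rows, columns=["name", "chrom", "strand", "start", "end"]
        ),
    )


def make_alignments(evidence: EvidenceWorld, path) -> str:
    """Materialize the evidence geometry as a coordinate-sorted, indexed
    BAM: each signal block becomes ``round(depth)`` identical full-length
    reads, so per-base coverage from the BAM reproduces the plateaus."""
    import pysam

    chroms = sorted(evidence.track.chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(evidence.track.chrom_lengths[c])} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    reads = []
    for p in evidence.peaks:
        depth = int(round(p.norm_coverage)) or 1
        for k in range(depth):
            reads.append((tid[p.chrom], p.start - 1, p.end - p.start + 1,
                          p.strand == "-", f"{p.name}_r{k}"))
    reads.sort(key=lambda r: (r[0], r[1]))
    path = str(path)
    with pysam.AlignmentFile(path, "wb", header=header) as bam:
        for rtid, pos, ln, rev, name in reads:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.reference_id = rtid
            a.reference_start = pos
            a.cigarstring = f"{ln}M"
            a.query_sequence = "A" * ln
            a.mapping_quality = 60
            a.flag = 16 if rev else 0
            bam.write(a)
    pysam.index(path)
    return path
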