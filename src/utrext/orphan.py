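"""Orphan peaks: clustering unassigned intergenic peaks into novel genes.

High-coverage intergenic peaks that no annotated gene can claim may mark
unannotated genes (or very long 3' UTRs).  To stop several exon peaks of
one hidden gene from each becoming a separate feature — and thus counting
independently in the UMI matrix — peaks on the same chromosome and strand
are chained into clusters by a maximum gap, clusters wider than a maximum
span are discarded, and each surviving cluster becomes one gene with one
exon per member peak.  Both limits default to annotation-derived values
(intron-length p75, median gene length) resolved by the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from intervaltree import IntervalTree

from .annotation_io import EXON, GENE, TRANSCRIPT, Feature, GenomeAnnotation
from .evidence import Peak

logger = logging.getLogger(__name__)

ORPHAN_SOURCE = "utrext_orphan"


@dataclass
class OrphanCluster:
    chrom: str
    strand: str
    member_peaks: list[Peak] = field(default_factory=list)
    cluster_id: str = ""

    @property
    def span_start(self) -> int:
        return min(p.start for p in self.member_peaks)

    @property
    def span_end(self) -> int:
        return max(p.end for p in self.member_peaks)

    @property
    def span_length(self) -> int:
        return self.span_end - self.span_start + 1


def cluster_orphan_peaks(
    peaks: Sequence[Peak], orphan_maxdist: float, nomerge: bool = False
) -> list[OrphanCluster]:
    """Single-linkage chaining of unassigned peaks.

    Peaks on the same chromosome and strand whose gap
    (``next.start - prev.end - 1``) is at most ``orphan_maxdist`` join one
    cluster.  With ``nomerge`` every peak becomes its own cluster.  The
    partition does not depend on input order.
    """
    ordered = sorted(peaks, key=lambda p: (p.chrom, p.strand, p.start, p.end))
    clusters: list[OrphanCluster] = []
    for p in ordered:
        if (
            not nomerge
            and clusters
            and clusters[-1].chrom == p.chrom
            and clusters[-1].strand == p.strand
            and p.start - clusters[-1].span_end - 1 <= orphan_maxdist
        ):
            clusters[-1].member_peaks.append(p)
        else:
            clusters.append(OrphanCluster(chrom=p.chrom, strand=p.strand, member_peaks=[p]))
    return clusters


def filter_clusters(
    clusters: Sequence[OrphanCluster], orphan_maxsize: float
) -> list[OrphanCluster]:
    """Drop clusters whose span exceeds ``orphan_maxsize``."""
    kept: list[OrphanCluster] = []
    for c in clusters:
        if c.span_length > orphan_maxsize:
            logger.info(
                "dropping orphan cluster %s:%d-%d (%s): span %d > maxsize %g",
                c.chrom, c.span_start, c.span_end, c.strand, c.span_length, orphan_maxsize,
            )
        else:
            kept.append(c)
    return kept


def emit_orphan_genes(
    clusters: Sequence[OrphanCluster], ann: GenomeAnnotation
) -> GenomeAnnotation:
    """Merge clusters into the annotation as novel gene features.

    Each cluster becomes one gene + one transcript spanning it, with one
    exon per member peak, IDs ``orphan_<n>`` numbered by genomic order and
    a distinguishable source column.  A cluster that overlaps a same-strand
    gene of the (possibly freshly extended) annotation is dropped with a
    warning; existing features are never altered.
    """
    out = ann.copy()
    trees: dict[tuple[str, str], IntervalTree] = {}
    for g in ann.genes():
        if g.strand in "+-":
            trees.setdefault((g.chrom, g.strand), IntervalTree()).addi(
                g.start - 1, g.end, g.feature_id
            )
    n = 0
    for c in sorted(clusters, key=lambda c: (c.chrom, c.span_start, c.span_end)):
        tree = trees.get((c.chrom, c.strand))
        if tree is not None and tree.overlap(c.span_start - 1, c.span_end):
            logger.warning(
                "dropping orphan cluster %s:%d-%d (%s): overlaps annotated gene",
                c.chrom, c.span_start, c.span_end, c.strand,
            )
            continue
        n += 1
        gid = f"orphan_{n}"
        c.cluster_id = gid
        tid = f"{gid}.t"
        out.add(
            Feature(gid, GENE, c.chrom, c.span_start, c.span_end, c.strand,
                    ftype="gene", source=ORPHAN_SOURCE)
        )
        out.add(
            Feature(tid, TRANSCRIPT, c.chrom, c.span_start, c.span_end, c.strand,
                    parent_id=gid, ftype="transcript", source=ORPHAN_SOURCE)
        )
        for k, p in enumerate(
            sorted(c.member_peaks, key=lambda p: (p.start, p.end)), start=1
        ):
            out.add(
                Feature(f"{tid}.exon{k}", EXON, c.chrom, p.start, p.end, c.strand,
                        parent_id=tid, ftype="exon", source=ORPHAN_SOURCE)
            )
    return out
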