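"""Resolution of same-strand gene-gene overlaps.

With 3'-biased reads, signal in a region where an upstream gene's 3' end
overlaps a downstream gene's 5' end almost certainly belongs to the
upstream gene's UTR, so the upstream gene keeps its full 3' region:
genes fully contained in a same-strand gene are removed, and (optionally)
downstream 5' ends are clipped to one bp past the upstream gene's 3' end.
Opposite-strand overlaps are biologically legitimate and never touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .annotation_io import GenomeAnnotation

logger = logging.getLogger(__name__)


@dataclass
class ClipRecord:
    gene_id: str
    old_5prime: int
    new_5prime: int
    clipped_bp: int
    upstream_gene_id: str


@dataclass
class ClipReport:
    records: list[ClipRecord] = field(default_factory=list)
    conflicts: list[str] = field(default_factory=list)  # genes a clip would consume

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.__dict__ for r in self.records],
            columns=["gene_id", "old_5prime", "new_5prime", "clipped_bp", "upstream_gene_id"],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def remove_contained_genes(
    ann: GenomeAnnotation,
) -> tuple[GenomeAnnotation, list[str]]:
    """Drop every gene fully contained in another same-strand gene.

    Two genes with identical spans: the lexicographically larger ID is
    removed with a warning.  Returns the pruned annotation and the removed
    gene IDs.
    """
    out = ann.copy()
    removed: list[str] = []
    by_group: dict[tuple[str, str], list] = {}
    for g in out.genes():
        by_group.setdefault((g.chrom, g.strand), []).append(g)
    for genes in by_group.values():
        genes.sort(key=lambda g: (g.start, -g.end, g.feature_id))
        for i, a in enumerate(genes):
            for b in genes:
                if a is b:
                    continue
                if b.start <= a.start and a.end <= b.end:
                    if (a.start, a.end) == (b.start, b.end):
                        # mutual containment: drop the larger ID once
                        if a.feature_id < b.feature_id:
                            continue
                        logger.warning(
                            "genes %s and %s have identical spans; removing %s",
                            b.feature_id, a.feature_id, a.feature_id,
                        )
                    removed.append(a.feature_id)
                    break
    for gid in removed:
        logger.info("removing contained gene %s", gid)
        out.remove(gid)
    return out, removed


def clip_5prime_overlaps(ann: GenomeAnnotation) -> tuple[GenomeAnnotation, ClipReport]:
    """Clip downstream genes' 5' ends out of same-strand overlaps.

    Genes are processed left-to-right in the strand sense; each gene's 5'
    boundary is moved to 1 bp past the largest 3' end among the genes
    already passed, and its transcript and exons follow (exons fully
    inside the clipped region are deleted, a straddling exon is
    truncated).  A clip that would consume a gene entirely leaves it
    unclipped and records a conflict.  For chains of three or more
    overlapping genes the outcome is order-dependent by construction.
    """
    out = ann.copy()
    report = ClipReport()
    by_group: dict[tuple[str, str], list] = {}
    for g in out.genes():
        if g.strand in "+-":
            by_group.setdefault((g.chrom, g.strand), []).append(g)

    for (chrom, strand), genes in by_group.items():
        if strand == "+":
            genes.sort(key=lambda g: (g.start, g.end, g.feature_id))
        else:
            genes.sort(key=lambda g: (-g.end, -g.start, g.feature_id))
        frontier = None  # most advanced 3' end seen, in strand sense
        frontier_gene = None
        for g in genes:
            if frontier is not None:
                overlap = (
                    g.start <= frontier if strand == "+" else g.end >= frontier
                )
                if overlap:
                    new5 = frontier + 1 if strand == "+" else frontier - 1
                    ok = new5 <= g.end if strand == "+" else new5 >= g.start
                    if not ok:
                        logger.warning(
                            "cannot clip gene %s: upstream gene %s covers it entirely",
                            g.feature_id, frontier_gene,
                        )
                        report.conflicts.append(g.feature_id)
                    else:
                        old5 = g.five_prime()
                        _apply_clip(out, g.feature_id, new5)
                        report.records.append(
                            ClipRecord(
                                gene_id=g.feature_id,
                                old_5prime=old5,
                                new_5prime=new5,
                                clipped_bp=abs(new5 - old5),
                                upstream_gene_id=frontier_gene,
                            )
                        )
            g3 = g.three_prime()
            if (
                frontier is None
                or (strand == "+" and g3 > frontier)
                or (strand == "-" and g3 < frontier)
            ):
                frontier, frontier_gene = g3, g.feature_id
    return out, report


def _apply_clip(ann: GenomeAnnotation, gene_id: str, new5: int) -> None:
    gene = ann[gene_id]
    if gene.strand == "+":
        gene.start = new5
    else:
        gene.end = new5
    for tx in ann.transcripts_of(gene_id):
        for exon in list(ann.exons_of(tx.feature_id)):
            if gene.strand == "+":
                if exon.end < new5:
                    ann.remove(exon.feature_id)
                elif exon.start < new5:
                    exon.start = new5
            else:
                if exon.start > new5:
                    ann.remove(exon.feature_id)
                elif exon.end > new5:
                    exon.end = new5
        if gene.strand == "+":
            tx.start = max(tx.start, new5)
        else:
            tx.end = min(tx.end, new5)


def count_same_strand_overlaps(ann: GenomeAnnotation) -> int:
    """Number of same-strand gene pairs whose spans overlap (diagnostic)."""
    n = 0
    by_group: dict[tuple[str, str], list] = {}
    for g in ann.genes():
        by_group.setdefault((g.chrom, g.strand), []).append(g)
    for genes in by_group.values():
        genes.sort(key=lambda g: g.start)
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                if b.start > a.end:
                    break
                n += 1
    return n
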