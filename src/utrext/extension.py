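"""Assignment of filtered intergenic peaks to genes and 3' extension.

Each surviving intergenic peak is offered to the nearest same-strand gene
whose 3' end lies upstream of it (never shared between genes, so UMIs are
not double counted).  A gene's 3' end then moves to the far edge of its
most distal assigned peak, clamped by the maximum extension distance
(``-m``) and by the start of the nearest same-strand downstream gene —
an extension never creates a new same-strand overlap.  The gene, its
retained transcript, and the terminal exon are all moved identically so
exon-overlap counters see contiguous 3' signal.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .annotation_io import GenomeAnnotation
from .evidence import Peak

logger = logging.getLogger(__name__)

CAP_NONE, CAP_MAX_DIST, CAP_DOWNSTREAM = "none", "max_dist", "downstream_gene"


@dataclass
class PipelineConfig:
    """User-tunable parameters of the full pipeline.

    ``orphan_maxdist`` / ``orphan_maxsize`` accept "auto", resolved at run
    time to the intron-length 75th percentile and the median gene length of
    the input annotation, respectively.
    """

    max_extension: int = 5000
    peak_perc: float = 25.0
    orphan: bool = False
    orphan_maxdist: Union[int, float, str] = "auto"
    orphan_maxsize: Union[int, float, str] = "auto"
    clip_5prime: bool = False
    nomerge: bool = False
    subsample_reads: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_extension <= 0:
            raise ValueError("max_extension must be positive")
        if not 0 <= self.peak_perc <= 100:
            raise ValueError("peak_perc must be in [0, 100]")


@dataclass
class ExtensionRecord:
    gene_id: str
    chrom: str
    strand: str
    old_3prime: int
    new_3prime: int
    extension_length: int
    cap_reason: str = CAP_NONE
    peak_id: Optional[str] = None


@dataclass
class ExtensionReport:
    records: list[ExtensionRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene_id": r.gene_id,
                    "chrom": r.chrom,
                    "strand": r.strand,
                    "old_3prime": r.old_3prime,
                    "new_3prime": r.new_3prime,
                    "extension_length": r.extension_length,
                    "cap_reason": r.cap_reason,
                    "peak_id": r.peak_id if r.peak_id is not None else "",
                }
                for r in self.records
            ],
            columns=[
                "gene_id",
                "chrom",
                "strand",
                "old_3prime",
                "new_3prime",
                "extension_length",
                "cap_reason",
                "peak_id",
            ],
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _genes_by_strand(ann: GenomeAnnotation):
    groups: dict[tuple[str, str], list] = {}
    for g in ann.genes():
        if g.strand in "+-":
            groups.setdefault((g.chrom, g.strand), []).append(g)
    return groups


def assign_peaks_to_genes(
    peaks: Sequence[Peak], ann: GenomeAnnotation, max_extension: int
) -> tuple[dict[str, list[Peak]], list[Peak]]:
    """Assign each filtered intergenic peak to at most one gene.

    A peak is assignable to gene G iff it shares chromosome and strand,
    lies strictly downstream of G's 3' end in the strand sense, starts
    within ``max_extension`` of that end, and no other same-strand gene
    sits between.  The nearest eligible upstream gene wins; leftover peaks
    are returned as orphan candidates.
    """
    groups = _genes_by_strand(ann)
    # sort genes by 3'-end coordinate for bisection
    indexed: dict[tuple[str, str], tuple[list[int], list]] = {}
    for key, genes in groups.items():
        genes.sort(key=lambda g: g.three_prime())
        indexed[key] = ([g.three_prime() for g in genes], genes)

    assigned: dict[str, list[Peak]] = {}
    unassigned: list[Peak] = []
    for p in peaks:
        key = (p.chrom, p.strand)
        if key not in indexed:
            unassigned.append(p)
            continue
        ends, genes = indexed[key]
        gene = None
        if p.strand == "+":
            # nearest gene with 3' end < peak.start
            i = bisect.bisect_left(ends, p.start) - 1
            if i >= 0:
                cand = genes[i]
                if p.start - cand.three_prime() <= max_extension:
                    gene = cand
        else:
            # nearest gene with 3' end (its start) > peak.end
            i = bisect.bisect_right(ends, p.end)
            if i < len(genes):
                cand = genes[i]
                if cand.three_prime() - p.end <= max_extension:
                    gene = cand
        if gene is None:
            unassigned.append(p)
        else:
            assigned.setdefault(gene.feature_id, []).append(p)
    return assigned, unassigned


def _downstream_limit(gene, neighbours: list) -> Optional[int]:
    """Coordinate 1 bp short of the nearest same-strand downstream gene."""
    if gene.strand == "+":
        starts = sorted(
            g.start for g in neighbours if g is not gene and g.start > gene.end
        )
        return starts[0] - 1 if starts else None
    ends = sorted(
        (g.end for g in neighbours if g is not gene and g.end < gene.start),
        reverse=True,
    )
    return ends[0] + 1 if ends else None


def extend_genes(
    ann: GenomeAnnotation,
    assignments: dict[str, list[Peak]],
    max_extension: int,
) -> tuple[GenomeAnnotation, ExtensionReport]:
    """Move each supported gene's 3' end to the far edge of its most distal
    assigned peak, clamped by ``max_extension`` and by the nearest
    same-strand downstream gene.  Downstream limits are computed on the
    input coordinates, so the result is independent of processing order.
    """
    out = ann.copy()
    groups = _genes_by_strand(ann)  # pre-extension coordinates for clamps
    report = ExtensionReport()
    for gene in sorted(out.genes(), key=lambda g: (g.chrom, g.start, g.feature_id)):
        if gene.strand not in "+-":
            continue
        old3 = gene.three_prime()
        rec = ExtensionRecord(
            gene_id=gene.feature_id,
            chrom=gene.chrom,
            strand=gene.strand,
            old_3prime=old3,
            new_3prime=old3,
            extension_length=0,
        )
        peaks = assignments.get(gene.feature_id, [])
        if peaks:
            neighbours = groups.get((gene.chrom, gene.strand), [])
            limit = _downstream_limit(ann[gene.feature_id], neighbours)
            if gene.strand == "+":
                distal = max(peaks, key=lambda p: p.end)
                far = distal.end
                target = min(far, old3 + max_extension)
                if limit is not None:
                    target = min(target, limit)
                new3 = max(old3, target)
                if new3 < far:
                    rec.cap_reason = (
                        CAP_DOWNSTREAM
                        if limit is not None and limit <= old3 + max_extension
                        else CAP_MAX_DIST
                    )
            else:
                distal = min(peaks, key=lambda p: p.start)
                far = distal.start
                target = max(far, old3 - max_extension)
                if limit is not None:
                    target = max(target, limit)
                new3 = min(old3, target)
                if new3 > far:
                    rec.cap_reason = (
                        CAP_DOWNSTREAM
                        if limit is not None and limit >= old3 - max_extension
                        else CAP_MAX_DIST
                    )
            rec.peak_id = distal.name or None
            rec.new_3prime = new3
            rec.extension_length = abs(new3 - old3)
            _apply_new_three_prime(out, gene.feature_id, new3)
        report.records.append(rec)
    return out, report


def _apply_new_three_prime(ann: GenomeAnnotation, gene_id: str, new3: int) -> None:
    """Move gene, retained transcript(s) and terminal exon 3' ends to new3."""
    gene = ann[gene_id]
    if gene.strand == "+":
        gene.end = max(gene.end, new3)
    else:
        gene.start = min(gene.start, new3)
    for tx in ann.transcripts_of(gene_id):
        exons = ann.exons_of(tx.feature_id)
        if gene.strand == "+":
            tx.end = max(tx.end, new3)
            if exons:
                terminal = max(exons, key=lambda e: e.end)
                terminal.end = max(terminal.end, new3)
        else:
            tx.start = min(tx.start, new3)
            if exons:
                terminal = min(exons, key=lambda e: e.start)
                terminal.start = min(terminal.start, new3)


def summarize_extensions(report: ExtensionReport) -> dict:
    """Counts and length distribution of nonzero extensions."""
    lengths = [r.extension_length for r in report.records if r.extension_length > 0]
    caps: dict[str, int] = {}
    for r in report.records:
        caps[r.cap_reason] = caps.get(r.cap_reason, 0) + 1
    return {
        "n_genes": len(report.records),
        "n_extended": len(lengths),
        "median_extension": float(np.median(lengths)) if lengths else None,
        "min_extension": min(lengths) if lengths else None,
        "max_extension": max(lengths) if lengths else None,
        "cap_reasons": caps,
    }
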