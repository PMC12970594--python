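"""End-to-end pipeline: annotation in, extended annotation out.

Stage order::

    parse -> repair -> longest isoform
          -> [contained-gene removal + 5' clipping, if enabled]
          -> annotation stats
          -> evidence (subsample -> coverage -> peak calling, or ingestion)
          -> classify -> percentile filter -> assign -> extend
          -> [orphan clustering, if enabled]
          -> write

Clipping runs before peak classification so genic/intergenic labels are
computed against resolved gene models.  Orphan clustering runs after
extension, on the peaks left unassigned, and re-checks collisions against
the extended annotation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import annotation_io as aio
from . import evidence as ev
from .evidence import CoverageTrack, Peak
from .extension import (
    ExtensionReport,
    PipelineConfig,
    assign_peaks_to_genes,
    extend_genes,
    summarize_extensions,
)
from .orphan import cluster_orphan_peaks, emit_orphan_genes, filter_clusters
from .overlap import ClipReport, clip_5prime_overlaps, remove_contained_genes

logger = logging.getLogger(__name__)


class EvidenceError(RuntimeError):
    """Raised when read evidence cannot be obtained or is inconsistent."""


@dataclass
class PipelineResult:
    annotation: aio.GenomeAnnotation
    extension_report: ExtensionReport
    summary: dict
    stats: aio.AnnotationStats
    clip_report: Optional[ClipReport] = None
    removed_genes: list[str] = field(default_factory=list)
    coverage_threshold: Optional[float] = None
    resolved_orphan_maxdist: Optional[float] = None
    resolved_orphan_maxsize: Optional[float] = None
    n_peaks: int = 0
    n_genic: int = 0
    n_intergenic: int = 0
    n_intergenic_kept: int = 0
    n_orphan_genes: int = 0


def _gather_evidence(
    config: PipelineConfig,
    bam=None,
    peaks_path=None,
    peaks_plus=None,
    peaks_minus=None,
    coverage_plus=None,
    coverage_minus=None,
    use_macs2: bool = False,
    tmpdir=None,
) -> list[Peak]:
    """Resolve one of the three evidence routes into coverage-annotated
    peaks: pre-called peak files, an external MACS2 run on a BAM, or the
    built-in caller on coverage from a BAM or bedGraph pair."""
    track: Optional[CoverageTrack] = None
    if bam is not None:
        if config.subsample_reads:
            bam = ev.subsample_alignments(
                bam, config.subsample_reads, seed=config.seed,
                out_path=(Path(tmpdir) / "subsampled.bam") if tmpdir else None,
            )
        track = ev.build_coverage(bam)
    elif coverage_plus is not None and coverage_minus is not None:
        track = ev.read_bedgraph_pair(coverage_plus, coverage_minus)

    peaks: list[Peak] = []
    if peaks_path or peaks_plus or peaks_minus:
        if peaks_path:
            peaks += ev.read_broadpeak(peaks_path)
        if peaks_plus:
            peaks += ev.read_broadpeak(peaks_plus, forced_strand="+")
        if peaks_minus:
            peaks += ev.read_broadpeak(peaks_minus, forced_strand="-")
        if track is None:
            raise EvidenceError(
                "pre-called peaks need a coverage source (BAM or bedGraph pair) "
                "to recompute peak coverage"
            )
    elif use_macs2:
        if bam is None:
            raise EvidenceError("MACS2 mode requires a BAM file")
        peaks = ev.call_peaks_macs2(bam, tmpdir=tmpdir)
    elif track is not None:
        for strand in "+-":
            peaks += ev.call_peaks(track, strand)
    else:
        raise EvidenceError(
            "no evidence provided: give a BAM, a bedGraph pair, or peak files"
        )
    if track is not None:
        ev.attach_coverage(peaks, track)
    return peaks


def run_pipeline(
    config: PipelineConfig,
    annotation_path,
    output_path=None,
    bam=None,
    peaks_path=None,
    peaks_plus=None,
    peaks_minus=None,
    coverage_plus=None,
    coverage_minus=None,
    out_dialect: Optional[str] = None,
    use_macs2: bool = False,
    classify_exons: bool = False,
    report_dir=None,
    tmpdir=None,
) -> PipelineResult:
    """Run the full extension pipeline; see the module docstring for the
    stage order.  Returns the in-memory result; ``output_path`` (and
    ``report_dir``) control what is written to disk."""
    ann = aio.parse_annotation(annotation_path)
    ann = aio.repair_hierarchy(ann)
    ann = aio.select_longest_isoform(ann)

    clip_report = None
    removed: list[str] = []
    if config.clip_5prime:
        ann, removed = remove_contained_genes(ann)
        ann, clip_report = clip_5prime_overlaps(ann)
        logger.info(
            "overlap resolution: removed %d contained genes, clipped %d 5' ends",
            len(removed), len(clip_report.records),
        )

    stats = aio.compute_annotation_stats(ann)
    maxdist = (
        stats.intron_length_p75
        if config.orphan_maxdist == "auto"
        else float(config.orphan_maxdist)
    )
    maxsize = (
        stats.median_gene_length
        if config.orphan_maxsize == "auto"
        else float(config.orphan_maxsize)
    )
    logger.info(
        "resolved orphan_maxdist=%g bp, orphan_maxsize=%g bp "
        "(intron p75=%g, median gene length=%g)",
        maxdist, maxsize, stats.intron_length_p75, stats.median_gene_length,
    )

    peaks = _gather_evidence(
        config,
        bam=bam,
        peaks_path=peaks_path,
        peaks_plus=peaks_plus,
        peaks_minus=peaks_minus,
        coverage_plus=coverage_plus,
        coverage_minus=coverage_minus,
        use_macs2=use_macs2,
        tmpdir=tmpdir,
    )
    ev.classify_peaks(peaks, ann, use_exons=classify_exons)
    n_genic = sum(p.classification == ev.GENIC for p in peaks)
    n_intergenic = sum(p.classification == ev.INTERGENIC for p in peaks)
    threshold = ev.genic_coverage_threshold(peaks, config.peak_perc)
    kept = ev.filter_intergenic_peaks(peaks, config.peak_perc)
    kept_intergenic = [p for p in kept if p.classification == ev.INTERGENIC]
    logger.info(
        "%d peaks: %d genic, %d intergenic; coverage threshold (p%g) = %s; "
        "%d intergenic peaks kept",
        len(peaks), n_genic, n_intergenic, config.peak_perc,
        f"{threshold:.4g}" if threshold is not None else "undefined",
        len(kept_intergenic),
    )

    assignments, unassigned = assign_peaks_to_genes(
        kept_intergenic, ann, config.max_extension
    )
    ann, report = extend_genes(ann, assignments, config.max_extension)
    summary = summarize_extensions(report)
    logger.info(
        "extended %d/%d genes (median extension %s bp)",
        summary["n_extended"], summary["n_genes"], summary["median_extension"],
    )

    n_orphans = 0
    if config.orphan:
        clusters = cluster_orphan_peaks(unassigned, maxdist, nomerge=config.nomerge)
        clusters = filter_clusters(clusters, maxsize)
        before = len(ann.genes())
        ann = emit_orphan_genes(clusters, ann)
        n_orphans = len(ann.genes()) - before
        logger.info("added %d orphan genes from %d clusters", n_orphans, len(clusters))

    if output_path is not None:
        aio.write_annotation(ann, output_path, dialect=out_dialect)
    if report_dir is not None:
        report_dir = Path(report_dir)
        report_dir.mkdir(parents=True, exist_ok=True)
        report.write_tsv(report_dir / "extension_report.tsv")
        if clip_report is not None:
            clip_report.write_tsv(report_dir / "clip_report.tsv")

    return PipelineResult(
        annotation=ann,
        extension_report=report,
        summary=summary,
        stats=stats,
        clip_report=clip_report,
        removed_genes=removed,
        coverage_threshold=threshold,
        resolved_orphan_maxdist=maxdist,
        resolved_orphan_maxsize=maxsize,
        n_peaks=len(peaks),
        n_genic=n_genic,
        n_intergenic=n_intergenic,
        n_intergenic_kept=len(kept_intergenic),
        n_orphan_genes=n_orphans,
    )
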