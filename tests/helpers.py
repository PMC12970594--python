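"""Shared fixture builders and independent oracles for the test suite.

The oracles here deliberately reimplement the quantities under test with
the most literal possible algorithms (per-base scans, closed-form
percentile interpolation, textbook Pearson) so that agreement with the
package is a genuine cross-check, not a tautology.
"""

from __future__ import annotations

import math

from utrext.annotation_io import EXON, GENE, TRANSCRIPT, Feature, GenomeAnnotation
from utrext.evidence import CoverageTrack, Peak


def make_ann(genes, dialect="gtf") -> GenomeAnnotation:
    """Build an annotation from tuples
    ``(gene_id, chrom, strand, start, end, [exon intervals])``.
    One transcript ``<gid>.t`` per gene; exons default to the full span."""
    ann = GenomeAnnotation(dialect=dialect)
    for gid, chrom, strand, start, end, *rest in genes:
        exons = rest[0] if rest else [(start, end)]
        tid = f"{gid}.t"
        ann.add(Feature(gid, GENE, chrom, start, end, strand, ftype="gene"))
        ann.add(Feature(tid, TRANSCRIPT, chrom, start, end, strand,
                        parent_id=gid, ftype="transcript"))
        for k, (es, ee) in enumerate(sorted(exons), start=1):
            ann.add(Feature(f"{tid}.exon{k}", EXON, chrom, es, ee, strand,
                            parent_id=tid, ftype="exon"))
    return ann


def make_peak(chrom, start, end, strand, norm=1.0, name="", classification="unset"):
    p = Peak(chrom=chrom, start=start, end=end, strand=strand, name=name,
             total_coverage=norm * (end - start + 1), norm_coverage=norm)
    p.classification = classification
    return p


def make_track(chrom_lengths, blocks) -> CoverageTrack:
    """blocks: (chrom, strand, start, end, depth), 1-based closed."""
    track = CoverageTrack(chrom_lengths)
    for chrom, strand, s, e, d in blocks:
        track.add_block(chrom, strand, s, e, d)
    return track


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------


def percentile_oracle(values, p) -> float:
    """Linear interpolation between order statistics, written longhand."""
    s = sorted(float(v) for v in values)
    if len(s) == 1:
        return s[0]
    h = (len(s) - 1) * p / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def poisson_threshold_oracle(mean: float, q: float) -> int:
    """Smallest d >= 1 with P(Poisson(mean) >= d) <= q, by direct summation."""
    if mean <= 0:
        return 1
    d = 0
    cdf = 0.0
    term = math.exp(-mean)  # P(X = 0)
    while True:
        cdf += term
        tail_next = 1.0 - cdf  # P(X >= d+1)
        if tail_next <= q:
            return max(1, d + 1)
        d += 1
        term *= mean / d
        if d > 10 * mean + 1000:  # pragma: no cover - safety valve
            raise RuntimeError("oracle failed to converge")


def runscan_peaks_oracle(track: CoverageTrack, strand: str, params) -> list[tuple]:
    """Exhaustive per-base reimplementation of the caller contract:
    threshold runs -> merge gaps < extsize -> drop short runs.
    Returns (chrom, start, end) tuples, 1-based closed."""
    total = sum(float(a.sum()) for a in track.depth[strand].values())
    length = sum(track.chrom_lengths.values())
    mean = total / length if length else 0.0
    if mean == 0:
        return []
    thr = poisson_threshold_oracle(mean, params.qvalue_threshold)
    out = []
    for chrom in sorted(track.depth[strand]):
        arr = track.depth[strand][chrom]
        runs = []
        i = 0
        while i < len(arr):
            if arr[i] >= thr:
                j = i
                while j + 1 < len(arr) and arr[j + 1] >= thr:
                    j += 1
                runs.append([i + 1, j + 1])
                i = j + 1
            else:
                i += 1
        merged = []
        for s, e in runs:
            if merged and s - merged[-1][1] - 1 < params.extsize:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s + 1 >= params.min_length:
                out.append((chrom, s, e))
    return out


def pearson_oracle(xs, ys) -> float:
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs) * sum((y - my) ** 2 for y in ys))
    return num / den


def same_strand_overlapping_pairs(ann: GenomeAnnotation) -> list[tuple[str, str]]:
    pairs = []
    genes = ann.genes()
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if (
                a.chrom == b.chrom
                and a.strand == b.strand
                and a.start <= b.end
                and b.start <= a.end
            ):
                pairs.append((a.feature_id, b.feature_id))
    return pairs
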