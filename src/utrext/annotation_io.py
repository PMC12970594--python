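"""Parsing, repair and serialization of GTF/GFF gene annotations.

Real-world annotations — especially for non-model organisms — frequently
violate the assumptions that single-cell quantification tools make: gene
rows are missing, transcripts reuse their parent gene's ID, rows appear in
arbitrary order, and exotic attributes confuse downstream parsers.  This
module reads any reasonable GTF or GFF3 dialect into a small in-memory
hierarchy (genes > transcripts > exons), repairs it into a consistent
one-ID-per-feature form, reduces each gene to its longest isoform, and
writes back a minimal, sorted annotation carrying only the attributes UMI
demultiplexers need (``gene_id``/``transcript_id`` for GTF, ``ID``/``Parent``
for GFF3).

Coordinates are 1-based closed throughout, the native GTF/GFF convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np
from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

#: canonical feature kinds
GENE, TRANSCRIPT, EXON, OTHER = "gene", "transcript", "exon", "other"

_KIND_MAP = {
    "gene": GENE,
    "transcript": TRANSCRIPT,
    "mrna": TRANSCRIPT,
    "exon": EXON,
}

_KIND_PRIORITY = {GENE: 0, TRANSCRIPT: 1, EXON: 2, OTHER: 3}


class AnnotationError(ValueError):
    """Raised for unrecoverable problems in an input annotation."""


@dataclass
class Feature:
    """One genomic feature (one row of a GTF/GFF file).

    ``start``/``end`` are 1-based closed.  ``kind`` is the canonical role in
    the hierarchy; ``ftype`` preserves the raw type column (e.g. ``CDS`` for
    kind ``other``).
    """

    feature_id: str
    kind: str
    chrom: str
    start: int
    end: int
    strand: str
    parent_id: Optional[str] = None
    ftype: str = ""
    source: str = "."
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise AnnotationError(
                f"feature {self.feature_id!r}: start {self.start} > end {self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def three_prime(self) -> int:
        """Strand-aware 3' coordinate (end on '+', start on '-')."""
        return self.end if self.strand != "-" else self.start

    def five_prime(self) -> int:
        return self.start if self.strand != "-" else self.end


@dataclass
class AnnotationStats:
    """Length statistics of a repaired, one-isoform annotation.

    These resolve the run-time "auto" defaults of orphan-peak clustering:
    the maximum within-cluster gap defaults to the 75th percentile of
    intron length, and the maximum cluster span to the median gene length.
    """

    intron_length_p75: float
    median_gene_length: float
    median_transcript_length: float
    n_introns: int = 0


class GenomeAnnotation:
    """Hierarchical feature set with parent/child links.

    Features are held in insertion order in ``features`` (id -> Feature);
    IDs are unique (parsing enforces this, resolving repairable collisions
    up front).  The hierarchy is navigated through ``children_of``.
    """

    def __init__(self, features: Iterable[Feature] = (), dialect: str = "gtf"):
        self.features: dict[str, Feature] = {}
        self.dialect = dialect
        for f in features:
            self.add(f)

    # -- container plumbing -------------------------------------------------

    def add(self, feat: Feature) -> None:
        if feat.feature_id in self.features:
            raise AnnotationError(f"duplicate feature ID {feat.feature_id!r}")
        self.features[feat.feature_id] = feat

    def remove(self, feature_id: str, cascade: bool = True) -> None:
        """Remove a feature and (by default) its descendants."""
        if cascade:
            for child in list(self.children_of(feature_id)):
                self.remove(child.feature_id, cascade=True)
        self.features.pop(feature_id, None)

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.features

    def __getitem__(self, feature_id: str) -> Feature:
        return self.features[feature_id]

    def copy(self) -> "GenomeAnnotation":
        ann = GenomeAnnotation(dialect=self.dialect)
        for f in self.features.values():
            ann.add(replace(f, attributes=dict(f.attributes)))
        return ann

    # -- hierarchy navigation ----------------------------------------------

    def genes(self) -> list[Feature]:
        return [f for f in self.features.values() if f.kind == GENE]

    def transcripts(self) -> list[Feature]:
        return [f for f in self.features.values() if f.kind == TRANSCRIPT]

    def children_of(self, feature_id: str, kind: Optional[str] = None) -> list[Feature]:
        out = [f for f in self.features.values() if f.parent_id == feature_id]
        if kind is not None:
            out = [f for f in out if f.kind == kind]
        return out

    def transcripts_of(self, gene_id: str) -> list[Feature]:
        return self.children_of(gene_id, TRANSCRIPT)

    def exons_of(self, transcript_id: str) -> list[Feature]:
        return sorted(
            self.children_of(transcript_id, EXON), key=lambda f: (f.start, f.end)
        )

    def cds_of(self, transcript_id: str) -> list[Feature]:
        return sorted(
            (
                f
                for f in self.children_of(transcript_id)
                if f.kind == OTHER and f.ftype.upper() == "CDS"
            ),
            key=lambda f: (f.start, f.end),
        )

    def canonical_tuples(self) -> set[tuple]:
        """Hashable view used for round-trip / equality checks."""
        return {
            (f.chrom, f.start, f.end, f.strand, f.kind, f.feature_id, f.parent_id)
            for f in self.features.values()
        }


# ---------------------------------------------------------------------------
# shared ID machinery
# ---------------------------------------------------------------------------


def _resolve_parents(feats: list[Feature]) -> dict[int, Optional[Feature]]:
    """Map ``id(feature) -> parent Feature`` resolved kind-aware, so a
    transcript sharing its gene's ID still links to the gene and an exon
    whose ``parent_id`` names both a gene and a transcript picks the
    transcript.  Must run *before* any renaming."""
    gene_by_id = {f.feature_id: f for f in feats if f.kind == GENE}
    tx_by_id = {f.feature_id: f for f in feats if f.kind == TRANSCRIPT}
    resolved: dict[int, Optional[Feature]] = {}
    for f in feats:
        if f.kind == TRANSCRIPT:
            resolved[id(f)] = gene_by_id.get(f.parent_id) if f.parent_id else None
        elif f.kind in (EXON, OTHER) and f.parent_id is not None:
            resolved[id(f)] = tx_by_id.get(f.parent_id) or gene_by_id.get(f.parent_id)
        else:
            resolved[id(f)] = None
    return resolved


def _uniquify_ids(feats: list[Feature]) -> None:
    """Make feature IDs globally unique in place.

    Priority gene > transcript > exon/other, then file order; later
    claimants of a taken ID get ``_1``, ``_2`` ... suffixes.  Parent links
    are re-pointed through object identity so children follow renames.
    """
    resolved = _resolve_parents(feats)
    used: set[str] = set()
    for f in sorted(feats, key=lambda f: _KIND_PRIORITY[f.kind]):
        if not f.feature_id:  # placeholder, named later by _assign_child_ids
            continue
        if f.feature_id not in used:
            used.add(f.feature_id)
            continue
        n = 1
        while f"{f.feature_id}_{n}" in used:
            n += 1
        new_id = f"{f.feature_id}_{n}"
        logger.warning("renaming duplicate ID %r -> %r", f.feature_id, new_id)
        f.feature_id = new_id
        used.add(new_id)
    for f in feats:
        p = resolved.get(id(f))
        if p is not None:
            f.parent_id = p.feature_id


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def _detect_dialect(attr_column: str) -> str:
    # GTF attributes look like:  key "value"; ...   GFF3 like:  key=value;...
    if "=" in attr_column.split(";")[0] and ' "' not in attr_column:
        return "gff3"
    return "gtf"


def _first(attrs, key) -> Optional[str]:
    vals = attrs.get(key)
    return vals[0] if vals else None


def parse_annotation(path, dialect_hint: Optional[str] = None) -> GenomeAnnotation:
    """Parse a GTF or GFF3 file into a :class:`GenomeAnnotation`.

    The dialect is auto-detected from the attribute column of the first
    data row unless ``dialect_hint`` ("gtf" or "gff3") is given.  Row order
    is irrelevant: children appearing before their parents parse
    identically to a sorted file.  In GTF, ``gene_id``/``transcript_id``
    are grouping keys, so gene (and even transcript) rows may be absent —
    missing genes are synthesized later by :func:`repair_hierarchy` — while
    in GFF3 an exon whose ``Parent`` points nowhere is a hard error.

    Raises :class:`AnnotationError` naming the line for an unparseable row,
    and listing the IDs for duplicated gene/transcript rows.
    """
    dialect = dialect_hint.lower() if dialect_hint else None
    raw: list[tuple[int, object]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(
                    f"{path}: line {lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            if dialect is None:
                dialect = _detect_dialect(cols[8])
            try:
                raw.append((lineno, feature_from_line(line)))
            except Exception as exc:
                raise AnnotationError(f"{path}: line {lineno}: {exc}") from exc
    dialect = dialect or "gtf"

    feats: list[Feature] = []
    seen: dict[tuple[str, str], str] = {}  # (kind, id) -> chrom of first sighting
    duplicates: set[str] = set()
    for lineno, gf in raw:
        kind = _KIND_MAP.get(gf.featuretype.lower(), OTHER)
        attrs = gf.attributes
        if dialect == "gff3":
            fid = _first(attrs, "ID") or ""
            parent = _first(attrs, "Parent")
        else:
            gene_id = _first(attrs, "gene_id")
            tx_id = _first(attrs, "transcript_id")
            if kind == GENE:
                fid, parent = gene_id, None
            elif kind == TRANSCRIPT:
                fid, parent = tx_id, gene_id
            else:  # exon / CDS rows group under their transcript
                fid, parent = "", tx_id
            if not fid and kind in (GENE, TRANSCRIPT):
                raise AnnotationError(
                    f"{path}: line {lineno}: {gf.featuretype} row lacks "
                    f"{'gene_id' if kind == GENE else 'transcript_id'}"
                )
        feat = Feature(
            feature_id=fid or "",
            kind=kind,
            chrom=gf.seqid,
            start=int(gf.start),
            end=int(gf.end),
            strand=gf.strand if gf.strand in "+-" else ".",
            parent_id=parent,
            ftype=gf.featuretype,
            source=gf.source or ".",
            attributes={k: v[0] for k, v in attrs.items()},
        )
        if feat.kind in (GENE, TRANSCRIPT) and feat.feature_id:
            key = (feat.kind, feat.feature_id)
            if key in seen:
                duplicates.add(feat.feature_id)
                continue
            seen[key] = feat.chrom
        feats.append(feat)
    if duplicates:
        raise AnnotationError(
            f"{path}: duplicate {'IDs' if len(duplicates) > 1 else 'ID'}: "
            + ", ".join(sorted(duplicates))
        )

    _synthesize_missing_transcripts(feats, dialect, path)
    _uniquify_ids(feats)
    _assign_child_ids(feats)
    return GenomeAnnotation(feats, dialect=dialect)


def _synthesize_missing_transcripts(feats: list[Feature], dialect: str, path) -> None:
    """GTF exon/CDS rows whose transcript_id has no transcript row get one
    synthesized from the union of their spans.  In GFF3 the same situation
    is a dangling reference and is fatal."""
    tx_ids = {f.feature_id for f in feats if f.kind == TRANSCRIPT}
    gene_ids = {f.feature_id for f in feats if f.kind == GENE}
    orphans: dict[str, list[Feature]] = {}
    dangling: list[str] = []
    for f in feats:
        if f.kind in (EXON, OTHER) and f.parent_id and f.parent_id not in tx_ids:
            if dialect == "gff3" and f.parent_id not in gene_ids:
                dangling.append(f.parent_id)
            elif dialect != "gff3":
                orphans.setdefault(f.parent_id, []).append(f)
    if dangling:
        raise AnnotationError(
            f"{path}: features reference missing parents: "
            + ", ".join(sorted(set(dangling)))
        )
    for tid, children in orphans.items():
        feats.append(
            Feature(
                feature_id=tid,
                kind=TRANSCRIPT,
                chrom=children[0].chrom,
                start=min(c.start for c in children),
                end=max(c.end for c in children),
                strand=children[0].strand,
                parent_id=children[0].attributes.get("gene_id"),
                ftype="transcript",
                source=children[0].source,
            )
        )


def _assign_child_ids(feats: list[Feature]) -> None:
    """Give ID-less exon/CDS rows deterministic IDs ``<tid>.exon1`` ...
    numbered in coordinate order (stable under row shuffling and across
    write/parse round trips)."""
    pending: dict[tuple[str, str], list[Feature]] = {}
    for f in feats:
        if not f.feature_id:
            tag = "exon" if f.kind == EXON else (f.ftype.lower() or "other")
            pending.setdefault((f.parent_id or "", tag), []).append(f)
    taken = {f.feature_id for f in feats if f.feature_id}
    for (tid, tag), group in pending.items():
        group.sort(key=lambda f: (f.start, f.end))
        n = 0
        for f in group:
            n += 1
            fid = f"{tid}.{tag}{n}"
            while fid in taken:
                n += 1
                fid = f"{tid}.{tag}{n}"
            f.feature_id = fid
            taken.add(fid)


# ---------------------------------------------------------------------------
# repair
# ---------------------------------------------------------------------------


def repair_hierarchy(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Return a repaired copy: every transcript gains a gene parent, IDs are
    globally unique, and parent spans contain their children.

    Missing genes are synthesized from the transcript's declared parent ID
    when present (grouping transcripts that share it), else named
    ``<transcript_id>_gene``.  ID collisions are resolved by priority
    gene > transcript > exon, so a transcript that reuses its gene's ID is
    renamed (``_1`` suffix) while the gene keeps it.  Transcripts without
    exon rows get a single exon spanning the transcript.  Idempotent.
    """
    feats = [replace(f, attributes=dict(f.attributes)) for f in ann.features.values()]

    # 1. parentless transcripts get a derived gene ID
    for f in feats:
        if f.kind == TRANSCRIPT and not f.parent_id:
            f.parent_id = f"{f.feature_id}_gene"

    # 2. synthesize missing gene features, grouping transcripts by parent ID
    gene_ids = {f.feature_id for f in feats if f.kind == GENE}
    missing: dict[str, list[Feature]] = {}
    for f in feats:
        if f.kind == TRANSCRIPT and f.parent_id not in gene_ids:
            missing.setdefault(f.parent_id, []).append(f)
    for gid, txs in missing.items():
        feats.append(
            Feature(
                feature_id=gid,
                kind=GENE,
                chrom=txs[0].chrom,
                start=min(t.start for t in txs),
                end=max(t.end for t in txs),
                strand=txs[0].strand,
                ftype="gene",
                source=txs[0].source,
            )
        )

    # 3. global ID uniqueness (gene wins ties; children follow renames)
    _uniquify_ids(feats)
    repaired = GenomeAnnotation(feats, dialect=ann.dialect)

    # 4. transcripts with no exon rows get one exon spanning the transcript
    for tx in repaired.transcripts():
        if not repaired.exons_of(tx.feature_id):
            repaired.add(
                Feature(
                    feature_id=f"{tx.feature_id}.exon1",
                    kind=EXON,
                    chrom=tx.chrom,
                    start=tx.start,
                    end=tx.end,
                    strand=tx.strand,
                    parent_id=tx.feature_id,
                    ftype="exon",
                    source=tx.source,
                )
            )

    # 5. grow parent spans to contain their children
    for tx in repaired.transcripts():
        exons = repaired.exons_of(tx.feature_id)
        tx.start = min([tx.start] + [e.start for e in exons])
        tx.end = max([tx.end] + [e.end for e in exons])
    for gene in repaired.genes():
        txs = repaired.transcripts_of(gene.feature_id)
        if txs:
            gene.start = min([gene.start] + [t.start for t in txs])
            gene.end = max([gene.end] + [t.end for t in txs])
    return repaired


def select_longest_isoform(ann: GenomeAnnotation) -> GenomeAnnotation:
    """Keep one transcript per gene: maximal summed exon length, ties broken
    by lexicographically smallest transcript ID.  The gene span shrinks to
    the retained transcript's span.  Genes without transcripts are dropped
    with a warning.
    """
    out = ann.copy()
    for gene in list(out.genes()):
        txs = out.transcripts_of(gene.feature_id)
        if not txs:
            logger.warning("dropping gene %s: no transcripts", gene.feature_id)
            out.remove(gene.feature_id)
            continue
        scored = sorted(
            txs,
            key=lambda t: (
                -sum(e.length for e in out.exons_of(t.feature_id)),
                t.feature_id,
            ),
        )
        for t in scored[1:]:
            out.remove(t.feature_id)
        gene.start, gene.end = scored[0].start, scored[0].end
    return out


def compute_annotation_stats(
    ann: GenomeAnnotation, intron_fallback: float = 1000.0
) -> AnnotationStats:
    """Intron-length 75th percentile plus median gene/transcript lengths.

    Introns are the gaps between consecutive exons of each transcript;
    percentiles use linear interpolation between order statistics.  An
    annotation with no introns reports the configured fallback p75.
    """
    introns: list[int] = []
    for tx in ann.transcripts():
        exons = ann.exons_of(tx.feature_id)
        for a, b in zip(exons, exons[1:]):
            gap = b.start - a.end - 1
            if gap > 0:
                introns.append(gap)
    gene_lengths = [g.length for g in ann.genes()]
    tx_lengths = [t.length for t in ann.transcripts()]
    if introns:
        p75 = float(np.percentile(introns, 75))
    else:
        logger.warning(
            "annotation has no introns; using fallback p75 = %s bp", intron_fallback
        )
        p75 = float(intron_fallback)
    return AnnotationStats(
        intron_length_p75=p75,
        median_gene_length=float(np.median(gene_lengths)) if gene_lengths else 0.0,
        median_transcript_length=float(np.median(tx_lengths)) if tx_lengths else 0.0,
        n_introns=len(introns),
    )


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def _sorted_for_output(ann: GenomeAnnotation) -> Iterator[Feature]:
    genes = sorted(ann.genes(), key=lambda g: (g.chrom, g.start, g.feature_id))
    for gene in genes:
        yield gene
        for tx in sorted(
            ann.transcripts_of(gene.feature_id), key=lambda t: (t.start, t.feature_id)
        ):
            yield tx
            yield from ann.exons_of(tx.feature_id)


def write_annotation(ann: GenomeAnnotation, path, dialect: Optional[str] = None) -> None:
    """Write gene/transcript/exon rows sorted by chromosome and start.

    Only the attributes quantification tools rely on are emitted:
    ``ID``/``Parent`` for GFF3, ``gene_id``/``transcript_id`` for GTF.
    CDS/UTR and other auxiliary rows are dropped.
    """
    dialect = (dialect or ann.dialect).lower()
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"unknown dialect {dialect!r}")
    tx_gene = {t.feature_id: t.parent_id for t in ann.transcripts()}
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
        for f in _sorted_for_output(ann):
            if dialect == "gff3":
                if f.kind == GENE:
                    attrs = f"ID={f.feature_id}"
                else:
                    attrs = f"ID={f.feature_id};Parent={f.parent_id}"
            else:
                if f.kind == GENE:
                    attrs = f'gene_id "{f.feature_id}";'
                elif f.kind == TRANSCRIPT:
                    attrs = f'gene_id "{f.parent_id}"; transcript_id "{f.feature_id}";'
                else:
                    gid = tx_gene.get(f.parent_id, "")
                    attrs = f'gene_id "{gid}"; transcript_id "{f.parent_id}";'
            fh.write(
                "\t".join(
                    [
                        f.chrom,
                        f.source or ".",
                        f.kind,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
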