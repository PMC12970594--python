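"""Annotation parsing, repair, isoform reduction, stats, serialization."""

import random

import numpy as np
import pytest

from helpers import make_ann, percentile_oracle
from utrext import annotation_io as aio
from utrext.annotation_io import AnnotationError
from utrext.simulate import make_genome

GTF_NO_GENES = """\
chr1\t.\ttranscript\t100\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr1\t.\texon\t100\t500\t.\t+\t.\tgene_id "g1"; transcript_id "t1";
chr2\t.\ttranscript\t200\t800\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
chr2\t.\texon\t200\t800\t.\t-\t.\tgene_id "g2"; transcript_id "t2";
"""

GFF3_ORDERED = """\
##gff-version 3
chr1\t.\tgene\t100\t900\t.\t+\t.\tID=gA
chr1\t.\tmRNA\t100\t900\t.\t+\t.\tID=tA;Parent=gA
chr1\t.\texon\t100\t300\t.\t+\t.\tID=eA1;Parent=tA
chr1\t.\texon\t600\t900\t.\t+\t.\tID=eA2;Parent=tA
chr1\t.\tgene\t2000\t2500\t.\t-\t.\tID=gB
chr1\t.\tmRNA\t2000\t2500\t.\t-\t.\tID=tB;Parent=gB
chr1\t.\texon\t2000\t2500\t.\t-\t.\tID=eB1;Parent=tB
"""


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestParse:
    def test_children_before_parents_parse_identically(self, tmp_path):
        ordered = _write(tmp_path, "a.gff3", GFF3_ORDERED)
        lines = [l for l in GFF3_ORDERED.splitlines() if not l.startswith("#")]
        shuffled = _write(
            tmp_path, "b.gff3", "##gff-version 3\n" + "\n".join(reversed(lines)) + "\n"
        )
        a = aio.parse_annotation(ordered)
        b = aio.parse_annotation(shuffled)
        assert a.canonical_tuples() == b.canonical_tuples()

    def test_gtf_without_gene_rows_parses(self, tmp_path):
        ann = aio.parse_annotation(_write(tmp_path, "x.gtf", GTF_NO_GENES))
        assert len(ann.genes()) == 0
        assert len(ann.transcripts()) == 2
        assert ann.dialect == "gtf"

    def test_duplicate_transcript_id_across_chromosomes_errors(self, tmp_path):
        text = GTF_NO_GENES.replace('transcript_id "t2"', 'transcript_id "t1"')
        with pytest.raises(AnnotationError, match="t1"):
            aio.parse_annotation(_write(tmp_path, "dup.gtf", text))

    def test_bad_column_count_errors_with_line_number(self, tmp_path):
        bad = GTF_NO_GENES + "chr1\tonly\tthree\n"
        with pytest.raises(AnnotationError, match="line 5"):
            aio.parse_annotation(_write(tmp_path, "bad.gtf", bad))

    def test_gff3_dangling_exon_parent_errors(self, tmp_path):
        text = GFF3_ORDERED + "chr1\t.\texon\t3000\t3100\t.\t+\t.\tID=eX;Parent=ghost\n"
        with pytest.raises(AnnotationError, match="ghost"):
            aio.parse_annotation(_write(tmp_path, "dangling.gff3", text))


class TestRepair:
    def test_orphan_transcripts_get_one_gene_each(self, tmp_path):
        ann = aio.parse_annotation(_write(tmp_path, "x.gtf", GTF_NO_GENES))
        rep = aio.repair_hierarchy(ann)
        assert len(rep.genes()) == 2
        for tx in rep.transcripts():
            gene = rep[tx.parent_id]
            assert gene.kind == "gene"
            assert (gene.start, gene.end) == (tx.start, tx.end)

    def test_transcript_reusing_gene_id_is_renamed(self, tmp_path):
        text = (
            'chr1\t.\tgene\t100\t500\t.\t+\t.\tgene_id "g1";\n'
            'chr1\t.\ttranscript\t100\t500\t.\t+\t.\tgene_id "g1"; transcript_id "g1";\n'
            'chr1\t.\texon\t100\t500\t.\t+\t.\tgene_id "g1"; transcript_id "g1";\n'
        )
        rep = aio.repair_hierarchy(aio.parse_annotation(_write(tmp_path, "n.gtf", text)))
        gene = rep["g1"]
        assert gene.kind == "gene"
        (tx,) = rep.transcripts()
        assert tx.feature_id == "g1_1"
        assert tx.parent_id == "g1"
        assert rep.exons_of("g1_1")

    def test_repair_is_idempotent_on_pathological_world(self, tmp_path):
        world = make_genome(n_genes=24, pathology_fraction=0.25, seed=9)
        world.write_gtf(tmp_path / "p.gtf", "original")
        rep = aio.repair_hierarchy(aio.parse_annotation(tmp_path / "p.gtf"))
        again = aio.repair_hierarchy(rep)
        assert rep.canonical_tuples() == again.canonical_tuples()

    def test_complete_annotation_unchanged(self):
        ann = make_ann([("g1", "chr1", "+", 100, 500)])
        assert aio.repair_hierarchy(ann).canonical_tuples() == ann.canonical_tuples()


class TestLongestIsoform:
    def _two_isoform_ann(self, lens=((100, 999),), second=((100, 1299),)):
        from utrext.annotation_io import EXON, TRANSCRIPT, Feature

        ann = make_ann([("g1", "chr1", "+", 100, 1300, [(100, 999)])])
        ann.add(Feature("t2", TRANSCRIPT, "chr1", 100, 1300, "+", parent_id="g1",
                        ftype="transcript"))
        ann.add(Feature("t2.exon1", EXON, "chr1", 100, 1299, "+", parent_id="t2",
                        ftype="exon"))
        return ann

    def test_longer_summed_exon_isoform_wins(self):
        ann = self._two_isoform_ann()
        out = aio.select_longest_isoform(ann)
        (tx,) = out.transcripts()
        assert tx.feature_id == "t2"  # 1200 bp of exon beats 900
        assert len(out.genes()) == len(out.transcripts())

    def test_tie_broken_by_smaller_transcript_id(self):
        ann = make_ann([("g1", "chr1", "+", 100, 1000, [(100, 599)])])
        from utrext.annotation_io import EXON, TRANSCRIPT, Feature

        # same 500 bp summed exon length, id sorts before "g1.t"
        ann.add(Feature("aB", TRANSCRIPT, "chr1", 200, 1000, "+", parent_id="g1",
                        ftype="transcript"))
        ann.add(Feature("aB.exon1", EXON, "chr1", 200, 699, "+", parent_id="aB",
                        ftype="exon"))
        out = aio.select_longest_isoform(ann)
        assert out.transcripts()[0].feature_id == "aB"

    def test_single_isoform_untouched_and_gene_span_shrinks(self):
        ann = make_ann([("g1", "chr1", "+", 100, 500)])
        ann["g1"].end = 900  # gene span wider than its only transcript
        out = aio.select_longest_isoform(ann)
        assert out["g1"].end == 500


class TestStats:
    def test_known_intron_percentile(self):
        # introns 100, 200, 300, 400 -> p75 by linear interpolation = 325
        exons = [(1000, 1099), (1200, 1299), (1500, 1599), (1900, 1999), (2400, 2499)]
        ann = make_ann([("g1", "chr1", "+", 1000, 2499, exons)])
        stats = aio.compute_annotation_stats(ann)
        assert stats.intron_length_p75 == pytest.approx(325.0)
        assert stats.n_introns == 4

    def test_single_gene_median_length(self):
        ann = make_ann([("g1", "chr1", "+", 1, 500)])
        stats = aio.compute_annotation_stats(ann)
        assert stats.median_gene_length == 500
        assert stats.median_transcript_length == 500

    def test_intronless_annotation_uses_fallback(self):
        ann = make_ann([("g1", "chr1", "+", 1, 500)])
        stats = aio.compute_annotation_stats(ann, intron_fallback=777)
        assert stats.intron_length_p75 == 777
        assert stats.n_introns == 0

    def test_percentiles_match_bruteforce_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            introns = rng.integers(1, 5000, size=rng.integers(1, 40)).tolist()
            exons, cursor = [], 1000
            for intron in introns + [0]:
                exons.append((cursor, cursor + 99))
                cursor += 100 + intron
            ann = make_ann([("g1", "chr1", "+", exons[0][0], exons[-1][1], exons)])
            stats = aio.compute_annotation_stats(ann)
            assert stats.intron_length_p75 == pytest.approx(
                percentile_oracle(introns, 75)
            )


class TestWrite:
    @pytest.mark.parametrize("dialect", ["gtf", "gff3"])
    def test_roundtrip_identity(self, tmp_path, dialect):
        world = make_genome(n_genes=16, pathology_fraction=0.25, seed=4)
        world.write_gtf(tmp_path / "w.gtf", "original")
        rep = aio.repair_hierarchy(aio.parse_annotation(tmp_path / "w.gtf"))
        out = tmp_path / f"out.{dialect}"
        aio.write_annotation(rep, out, dialect=dialect)
        again = aio.parse_annotation(out)
        expected = {t for t in rep.canonical_tuples() if t[4] != "other"}
        assert again.canonical_tuples() == expected

    def test_exotic_attributes_stripped(self, tmp_path):
        text = 'chr1\t.\tgene\t1\t99\t.\t+\t.\tID=g1;note=scary;Alias=foo\n'
        ann = aio.repair_hierarchy(
            aio.parse_annotation(_write(tmp_path, "x.gff3", text))
        )
        for dialect, allowed in (
            ("gff3", {"ID", "Parent"}),
            ("gtf", {"gene_id", "transcript_id"}),
        ):
            out = tmp_path / f"o.{dialect}"
            aio.write_annotation(ann, out, dialect=dialect)
            for line in out.read_text().splitlines():
                if line.startswith("#"):
                    continue
                attrs = line.split("\t")[8]
                keys = {
                    chunk.strip().split("=")[0].split(" ")[0]
                    for chunk in attrs.split(";")
                    if chunk.strip()
                }
                assert keys <= allowed

    def test_coordinate_columns_identical_across_dialects(self, tmp_path):
        world = make_genome(n_genes=10, seed=1)
        aio.write_annotation(world.original, tmp_path / "a.gtf", dialect="gtf")
        aio.write_annotation(world.original, tmp_path / "a.gff3", dialect="gff3")
        gtf = [l.split("\t")[:8] for l in (tmp_path / "a.gtf").read_text().splitlines()]
        gff = [
            l.split("\t")[:8]
            for l in (tmp_path / "a.gff3").read_text().splitlines()
            if not l.startswith("#")
        ]
        assert gtf == gff

    def test_shuffled_input_roundtrips(self, tmp_path):
        world = make_genome(n_genes=12, pathology_fraction=0.25, seed=8)
        world.write_gtf(tmp_path / "w.gtf", "original")
        lines = (tmp_path / "w.gtf").read_text().splitlines()
        random.Random(3).shuffle(lines)
        (tmp_path / "shuf.gtf").write_text("\n".join(lines) + "\n")
        a = aio.parse_annotation(tmp_path / "w.gtf")
        b = aio.parse_annotation(tmp_path / "shuf.gtf")
        assert a.canonical_tuples() == b.canonical_tuples()
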