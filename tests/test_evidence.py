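"""Coverage building, peak calling, broadPeak ingestion, classification,
and the genic-coverage percentile filter."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from helpers import (
    make_ann,
    make_peak,
    make_track,
    percentile_oracle,
    runscan_peaks_oracle,
)
from utrext import evidence as ev
from utrext.evidence import PeakCallParams


def _write_bam(path, reads, chrom_lengths={"chr1": 10000}):
    """reads: (chrom, pos0, cigar, is_reverse)"""
    chroms = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, (chrom, pos, cigar, rev) in enumerate(
            sorted(reads, key=lambda r: (r[0], r[1]))
        ):
            a = pysam.AlignedSegment()
            a.query_name = f"r{i}"
            a.reference_id = tid[chrom]
            a.reference_start = pos
            a.cigarstring = cigar
            a.query_sequence = "A" * sum(
                int(n) for n, op in _cigar_ops(cigar) if op in "MIS=X"
            )
            a.mapping_quality = 60
            a.flag = 16 if rev else 0
            bam.write(a)
    pysam.index(str(path))
    return str(path)


def _cigar_ops(cigar):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield num, ch
            num = ""


class TestBuildCoverage:
    def test_single_plus_read(self, tmp_path):
        bam = _write_bam(tmp_path / "a.bam", [("chr1", 99, "50M", False)])
        track = ev.build_coverage(bam)
        plus = track.depth["+"]["chr1"]
        assert plus[99:149].tolist() == [1.0] * 50
        assert plus.sum() == 50
        assert track.depth["-"]["chr1"].sum() == 0
        assert track.total_reads == 1

    def test_spliced_read_skips_the_gap(self, tmp_path):
        # blocks [100,119] and [200,239] 1-based; gap contributes nothing
        bam = _write_bam(tmp_path / "a.bam", [("chr1", 99, "20M80N40M", True)])
        track = ev.build_coverage(bam)
        minus = track.depth["-"]["chr1"]
        assert minus[99:119].tolist() == [1.0] * 20
        assert minus[119:199].sum() == 0
        assert minus[199:239].tolist() == [1.0] * 40

    def test_empty_bam(self, tmp_path):
        bam = _write_bam(tmp_path / "a.bam", [])
        track = ev.build_coverage(bam)
        assert track.total_reads == 0
        assert all(a.sum() == 0 for d in track.depth.values() for a in d.values())


class TestSubsample:
    def test_noop_when_under_target(self, tmp_path):
        bam = _write_bam(tmp_path / "a.bam", [("chr1", i * 10, "20M", False) for i in range(50)])
        assert ev.subsample_alignments(bam, 10000, seed=1) == bam

    def test_zero_target_rejected(self, tmp_path):
        bam = _write_bam(tmp_path / "a.bam", [("chr1", 0, "20M", False)])
        with pytest.raises(ValueError):
            ev.subsample_alignments(bam, 0, seed=1)

    def test_binomial_bounds_and_reproducibility(self, tmp_path):
        reads = [("chr1", (i * 7) % 9000, "20M", i % 2 == 0) for i in range(100_000)]
        bam = _write_bam(tmp_path / "big.bam", reads)
        out1 = ev.subsample_alignments(bam, 10_000, seed=5, out_path=tmp_path / "s1.bam")
        out2 = ev.subsample_alignments(bam, 10_000, seed=5, out_path=tmp_path / "s2.bam")
        n1 = ev.build_coverage(out1).total_reads
        n2 = ev.build_coverage(out2).total_reads
        assert n1 == n2  # same seed, same survivors
        assert abs(n1 - 10_000) <= 500


class TestCallPeaks:
    def test_single_block_called_whole(self):
        track = make_track({"chr1": 10000}, [("chr1", "+", 2001, 2500, 10)])
        peaks = ev.call_peaks(track, "+")
        assert [(p.start, p.end) for p in peaks] == [(2001, 2500)]
        assert peaks[0].norm_coverage == pytest.approx(10.0)
        assert peaks[0].total_coverage == pytest.approx(5000.0)

    def test_nearby_blocks_merge_within_extsize(self):
        track = make_track(
            {"chr1": 10000},
            [("chr1", "+", 1000, 1199, 10), ("chr1", "+", 1250, 1449, 10)],
        )
        peaks = ev.call_peaks(track, "+")  # 50 bp gap < extsize 100
        assert [(p.start, p.end) for p in peaks] == [(1000, 1449)]

    def test_short_runs_discarded(self):
        track = make_track({"chr1": 10000}, [("chr1", "+", 5000, 5019, 50)])
        assert ev.call_peaks(track, "+") == []  # 20 bp < min_length 30

    def test_empty_track_yields_nothing(self):
        track = make_track({"chr1": 5000}, [])
        assert ev.call_peaks(track, "+") == []

    def test_matches_runscan_oracle_on_random_tracks(self):
        rng = np.random.default_rng(123)
        params = PeakCallParams()
        for _ in range(100):
            n = int(rng.integers(500, 10_000))
            arr = np.zeros(n)
            for _ in range(rng.integers(1, 12)):
                s = int(rng.integers(0, n - 50))
                w = int(rng.integers(10, 400))
                arr[s : min(n, s + w)] += float(rng.integers(1, 60))
            track = make_track({"chrR": n}, [])
            track.depth["+"]["chrR"] = arr
            got = [(p.chrom, p.start, p.end) for p in ev.call_peaks(track, "+", params)]
            assert got == runscan_peaks_oracle(track, "+", params)

    def test_peak_coverage_never_exceeds_track_total(self):
        rng = np.random.default_rng(7)
        arr = rng.integers(0, 30, size=4000).astype(float)
        track = make_track({"chr1": 4000}, [])
        track.depth["+"]["chr1"] = arr
        peaks = ev.call_peaks(track, "+")
        assert sum(p.total_coverage for p in peaks) <= arr.sum() + 1e-9


class TestBroadPeak:
    def test_coordinate_conversion(self, tmp_path):
        f = tmp_path / "p.broadPeak"
        f.write_text("chr1\t999\t1499\tp1\t0\t+\t5.0\t-1\t-1\n")
        (p,) = ev.read_broadpeak(f)
        assert (p.chrom, p.start, p.end, p.strand) == ("chr1", 1000, 1499, "+")

    def test_dot_strand_needs_override(self, tmp_path):
        f = tmp_path / "p.broadPeak"
        f.write_text("chr1\t0\t100\tp1\t0\t.\t5.0\t-1\t-1\n")
        (p,) = ev.read_broadpeak(f, forced_strand="-")
        assert p.strand == "-"
        with pytest.raises(ValueError):
            ev.read_broadpeak(f)

    def test_empty_file(self, tmp_path):
        f = tmp_path / "p.broadPeak"
        f.write_text("")
        assert ev.read_broadpeak(f) == []

    def test_malformed_row_names_line(self, tmp_path):
        f = tmp_path / "p.broadPeak"
        f.write_text("chr1\t0\t100\tp1\t0\t+\n" "chr1\tnope\t100\tp2\t0\t+\n")
        with pytest.raises(ValueError, match="line 2"):
            ev.read_broadpeak(f)

    def test_coverage_recomputed_from_track(self, tmp_path):
        f = tmp_path / "p.broadPeak"
        f.write_text("chr1\t99\t199\tp1\t0\t+\t999.0\t-1\t-1\n")  # bogus coverage col
        (p,) = ev.read_broadpeak(f)
        track = make_track({"chr1": 1000}, [("chr1", "+", 100, 199, 3)])
        ev.attach_coverage([p], track)
        assert p.total_coverage == pytest.approx(300.0)
        assert p.norm_coverage == pytest.approx(3.0)


class TestClassify:
    ann = make_ann([("g1", "chr1", "+", 1000, 2000)])

    def test_same_strand_overlap_is_genic(self):
        (p,) = ev.classify_peaks([make_peak("chr1", 1500, 1600, "+")], self.ann)
        assert p.classification == "genic"

    def test_opposite_strand_overlap_is_intergenic(self):
        (p,) = ev.classify_peaks([make_peak("chr1", 1500, 1600, "-")], self.ann)
        assert p.classification == "intergenic"

    def test_one_bp_past_gene_end_is_intergenic(self):
        boundary = ev.classify_peaks(
            [make_peak("chr1", 2001, 2100, "+"), make_peak("chr1", 2000, 2100, "+")],
            self.ann,
        )
        assert [p.classification for p in boundary] == ["intergenic", "genic"]

    def test_conservation(self):
        peaks = [make_peak("chr1", s, s + 50, "+") for s in range(500, 3000, 200)]
        out = ev.classify_peaks(peaks, self.ann)
        assert len(out) == len(peaks)
        assert all(p.classification in ("genic", "intergenic") for p in out)


class TestPercentileFilter:
    def _peaks(self, genic_norms, intergenic_norms):
        peaks = [
            make_peak("chr1", 10 + i * 100, 60 + i * 100, "+", norm=v,
                      classification="genic")
            for i, v in enumerate(genic_norms)
        ]
        peaks += [
            make_peak("chr2", 10 + i * 100, 60 + i * 100, "+", norm=v,
                      classification="intergenic", name=f"ig{i}")
            for i, v in enumerate(intergenic_norms)
        ]
        return peaks

    def test_threshold_is_strict(self):
        peaks = self._peaks([1, 2, 3, 4, 5], [2.5, 2.0])
        assert ev.genic_coverage_threshold(peaks, 25) == pytest.approx(2.0)
        kept = ev.filter_intergenic_peaks(peaks, 25)
        names = [p.name for p in kept if p.classification == "intergenic"]
        assert names == ["ig0"]  # 2.5 kept, 2.0 (== threshold) dropped

    def test_percentile_zero_keeps_above_minimum(self):
        peaks = self._peaks([1, 2, 3], [0.5, 1.0, 1.5])
        kept = ev.filter_intergenic_peaks(peaks, 0)
        names = [p.name for p in kept if p.classification == "intergenic"]
        assert names == ["ig2"]  # only > min(genic) survives

    def test_no_intergenic_peaks_passthrough(self):
        peaks = self._peaks([1, 2, 3], [])
        assert ev.filter_intergenic_peaks(peaks, 25) == peaks

    def test_no_genic_peaks_keeps_all_with_warning(self, caplog):
        peaks = self._peaks([], [1.0, 2.0])
        with caplog.at_level("WARNING"):
            kept = ev.filter_intergenic_peaks(peaks, 25)
        assert len(kept) == 2
        assert any("NO GENIC PEAKS" in r.message for r in caplog.records)

    def test_threshold_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            genic = rng.uniform(0, 100, size=rng.integers(1, 40)).tolist()
            perc = float(rng.uniform(0, 100))
            peaks = self._peaks(genic, [])
            assert ev.genic_coverage_threshold(peaks, perc) == pytest.approx(
                percentile_oracle(genic, perc)
            )

    @settings(max_examples=50, derandomize=True)
    @given(
        genic=st.lists(st.floats(0, 1000, allow_nan=False), min_size=1, max_size=30),
        perc=st.floats(0, 100, allow_nan=False),
    )
    def test_threshold_property_matches_oracle(self, genic, perc):
        peaks = self._peaks(genic, [])
        assert ev.genic_coverage_threshold(peaks, perc) == pytest.approx(
            percentile_oracle(genic, perc), abs=1e-9
        )

    def test_raising_percentile_never_increases_survivors(self):
        rng = np.random.default_rng(2)
        peaks = self._peaks(
            rng.uniform(0, 50, size=30).tolist(), rng.uniform(0, 50, size=30).tolist()
        )
        survivors = [
            sum(
                p.classification == "intergenic"
                for p in ev.filter_intergenic_peaks(peaks, perc)
            )
            for perc in range(0, 101, 5)
        ]
        assert survivors == sorted(survivors, reverse=True)
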