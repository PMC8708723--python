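"""Interval algebra, coordinate conventions, and format round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regnet.genome import (
    GenomicInterval,
    Peak,
    SignalTrack,
    TssRecord,
    ValidationError,
    assign_ranks,
    distance_to_nearest_tss,
    merge_intervals,
    overlap_query,
)
from regnet import io as rio


def random_intervals(rng, n, chrom_len=10_000, chroms=("chr1",)):
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, chrom_len - 1))
        end = int(rng.integers(start + 1, min(start + 500, chrom_len) + 1))
        out.append(GenomicInterval(chrom, start, end))
    return out


def coverage(intervals, chrom_len=10_000, chrom="chr1"):
    cov = np.zeros(chrom_len, dtype=bool)
    for iv in intervals:
        if iv.chrom == chrom:
            cov[iv.start : iv.end] = True
    return cov


class TestIntervalValidation:
    def test_rejects_inverted_and_negative(self):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValidationError):
            GenomicInterval("", 0, 100)

    def test_summit_must_fall_inside_peak(self):
        iv = GenomicInterval("chr1", 100, 200)
        with pytest.raises(ValidationError):
            Peak(iv, summit_offset=100)
        assert Peak(iv, summit_offset=50).center == 150

    def test_center_prefers_summit_over_midpoint(self):
        p = Peak(GenomicInterval("chr1", 400, 600))
        assert p.center == 500
        p2 = Peak(GenomicInterval("chr1", 400, 600), summit_offset=10)
        assert p2.center == 410


class TestMerge:
    def test_overlapping_intervals_fuse(self):
        merged = merge_intervals(
            [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 150, 300)]
        )
        assert merged == [GenomicInterval("chr1", 100, 300)]

    def test_different_chromosomes_stay_separate(self):
        ivs = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr2", 100, 200)]
        assert merge_intervals(ivs) == ivs

    def test_touching_intervals_merge(self):
        merged = merge_intervals(
            [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 200, 300)]
        )
        assert merged == [GenomicInterval("chr1", 100, 300)]

    def test_coverage_preserved_on_random_input(self, rng):
        ivs = random_intervals(rng, 500)
        merged = merge_intervals(ivs)
        assert np.array_equal(coverage(ivs), coverage(merged))
        # disjoint and sorted
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start or a.chrom != b.chrom

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)), max_size=40))
    def test_merge_is_idempotent(self, spans):
        ivs = [GenomicInterval("chr1", s, s + l) for s, l in spans]
        once = merge_intervals(ivs)
        assert merge_intervals(once) == once


class TestOverlapQuery:
    def test_half_open_adjacency_is_not_overlap(self):
        assert overlap_query(
            GenomicInterval("chr1", 100, 200), [GenomicInterval("chr1", 200, 300)]
        ) == []

    def test_overlap_size_reported(self):
        hits = overlap_query(
            GenomicInterval("chr1", 100, 200), [GenomicInterval("chr1", 150, 250)]
        )
        assert len(hits) == 1 and hits[0][1] == 50

    def test_matches_quadratic_scan(self, rng):
        subjects = random_intervals(rng, 300, chroms=("chr1", "chr2"))
        queries = random_intervals(rng, 200, chroms=("chr1", "chr2"))
        for q in queries:
            expected = sorted(
                (s, q.overlap_bp(s)) for s in subjects if q.overlaps(s)
            )
            got = sorted(overlap_query(q, subjects))
            assert got == expected


class TestNearestTss:
    TSS = [
        TssRecord("gB", "chr1", 650, "+"),
        TssRecord("gA", "chr1", 500, "+"),
        TssRecord("gC", "chr2", 100, "-"),
    ]

    def test_exact_hit_distance_zero(self):
        p = Peak(GenomicInterval("chr1", 400, 600))  # center 500
        assert distance_to_nearest_tss(p, self.TSS) == ("gA", 0)

    def test_sign_is_strand_aware(self):
        # center 560: 60 downstream of gA on + strand
        p = Peak(GenomicInterval("chr1", 460, 660))
        assert distance_to_nearest_tss(p, self.TSS) == ("gA", 60)
        # on the minus strand, a center above the TSS is upstream (negative)
        p2 = Peak(GenomicInterval("chr2", 60, 160))  # center 110, TSS 100, '-'
        assert distance_to_nearest_tss(p2, self.TSS) == ("gC", -10)

    def test_missing_chromosome_is_an_error(self):
        with pytest.raises(ValidationError):
            distance_to_nearest_tss(Peak(GenomicInterval("chrX", 0, 10)), self.TSS)

    def test_matches_exhaustive_minimization(self, rng):
        tss = [
            TssRecord(f"g{i:03d}", "chr1", int(rng.integers(0, 10_000)), "+")
            for i in range(50)
        ]
        for _ in range(200):
            p = Peak(*[random_intervals(rng, 1)[0]])
            gene, dist = distance_to_nearest_tss(p, tss)
            best = min(abs(p.center - t.position) for t in tss)
            assert abs(dist) == best

    def test_shift_invariance(self, rng):
        tss = [TssRecord("g1", "chr1", 3000, "+"), TssRecord("g2", "chr1", 7000, "-")]
        shifted = [
            TssRecord(t.gene_id, t.chrom, t.position + 137, t.strand) for t in tss
        ]
        for iv in random_intervals(rng, 50):
            p, ps = Peak(iv), Peak(iv.shifted(137))
            assert distance_to_nearest_tss(p, tss) == distance_to_nearest_tss(ps, shifted)


class TestPeakIO:
    def test_narrowpeak_field_mapping(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t0\t.\t5.0\t10.0\t8.0\t50\n")
        (peak,) = rio.read_peaks(path)
        assert (peak.chrom, peak.start, peak.end) == ("chr1", 100, 200)
        assert peak.summit_offset == 50 and peak.score == 5.0

    def test_empty_file_yields_empty_set(self, tmp_path):
        path = tmp_path / "empty.narrowPeak"
        path.write_text("")
        assert rio.read_peaks(path) == []

    def test_ranks_assigned_by_descending_score(self, tmp_path):
        path = tmp_path / "a.narrowPeak"
        path.write_text(
            "chr1\t100\t200\tlow\t0\t.\t3.0\t-1\t-1\t-1\n"
            "chr1\t500\t600\thigh\t0\t.\t9.0\t-1\t-1\t-1\n"
        )
        peaks = {p.name: p.rank for p in rio.read_peaks(path)}
        assert peaks == {"high": 1, "low": 2}

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text("chr1\t100\t200\tp1\t0\t.\t5.0\t-1\t-1\t-1\nchr1\t300\n")
        with pytest.raises(rio.ParseError, match=":2:"):
            rio.read_peaks(path)

    def test_inverted_coordinates_rejected(self, tmp_path):
        path = tmp_path / "bad.narrowPeak"
        path.write_text("chr1\t200\t100\tp1\t0\t.\t5.0\t-1\t-1\t-1\n")
        with pytest.raises(rio.ParseError, match="end"):
            rio.read_peaks(path)

    def test_narrowpeak_round_trip(self, tmp_path, rng):
        peaks = []
        for i, iv in enumerate(random_intervals(rng, 100)):
            peaks.append(
                Peak(iv, name=f"p{i}", score=round(float(rng.uniform(0, 10)), 3),
                     summit_offset=int(rng.integers(iv.length)))
            )
        assign_ranks(peaks)
        path = tmp_path / "rt.narrowPeak"
        rio.write_peaks(peaks, path)
        back = rio.read_peaks(path)
        key = lambda p: (p.chrom, p.start, p.end, p.name, p.score, p.summit_offset)
        assert sorted(map(key, back)) == sorted(map(key, peaks))


class TestTrackIO:
    def test_bedgraph_round_trip(self, tmp_path, rng):
        starts = np.sort(rng.choice(np.arange(0, 10_000, 20), size=25, replace=False))
        records = [
            ("chr1", int(s), int(s) + 10, round(float(rng.uniform(0, 5)), 4))
            for s in starts
        ]
        track = SignalTrack.from_records(records)
        path = tmp_path / "t.bedGraph"
        rio.write_bedgraph(track, path)
        back = rio.read_bedgraph(path)
        assert list(back.records()) == list(track.records())

    def test_empty_track_round_trip(self, tmp_path):
        path = tmp_path / "e.bedGraph"
        rio.write_bedgraph(SignalTrack(), path)
        assert list(rio.read_bedgraph(path).records()) == []

    def test_overlapping_track_intervals_rejected(self):
        with pytest.raises(ValidationError):
            SignalTrack({"chr1": ([0, 5], [10, 15], [1.0, 2.0])})

    def test_mean_and_max_treat_uncovered_as_zero(self):
        track = SignalTrack.from_records([("chr1", 100, 150, 4.0)])
        assert track.mean_over("chr1", 100, 200) == pytest.approx(2.0)
        assert track.max_over("chr1", 100, 200) == 4.0
        assert track.mean_over("chr1", 300, 400) == 0.0


class TestGtfBoundary:
    def test_one_based_conversion_preserves_tss(self, tmp_path):
        # gene on + at 1-based 1001 -> 0-based 1000; '-' gene TSS at its end
        path = tmp_path / "genes.gtf"
        path.write_text(
            'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "gPlus";\n'
            'chr1\tsrc\tgene\t5001\t6000\t.\t-\t.\tgene_id "gMinus";\n'
            'chr1\tsrc\texon\t1001\t1100\t.\t+\t.\tgene_id "gPlus";\n'
        )
        tss = {t.gene_id: t.position for t in rio.read_gtf_tss(path)}
        assert tss == {"gPlus": 1000, "gMinus": 5999}
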