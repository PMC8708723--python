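"""cCRE classification rules, peak-set class distribution, signal matrices."""

import numpy as np
import pytest

from regnet.ccre import (
    AssaySignals,
    CcreClass,
    CcreParams,
    CcreRecord,
    assign_peak_classes,
    class_distribution,
    classify_element,
    compute_max_z,
    peakset_class_distribution,
    signal_matrix,
)
from regnet.genome import Genome, GenomicInterval, Peak, SignalTrack, TssRecord, ValidationError
from regnet.simulate import SimConfig, simulate_annotation, simulate_target_peaks

TSS = [TssRecord("g1", "chr1", 10_000, "+")]


def iv(center, width=300, chrom="chr1"):
    return GenomicInterval(chrom, center - width // 2, center - width // 2 + width)


class TestMaxZ:
    def test_zero_variance_is_an_error(self):
        track = SignalTrack.from_records([("chr1", 0, 10_000, 2.0)])
        elements = [iv(1000), iv(5000)]
        with pytest.raises(ValidationError, match="variance"):
            compute_max_z(elements, track)

    def test_two_elements_standardize_to_plus_minus_one(self):
        track = SignalTrack.from_records([("chr1", 900, 1100, 1.0), ("chr1", 4900, 5100, 3.0)])
        z = compute_max_z([iv(1000), iv(5000)], track)
        assert z == pytest.approx([-1.0, 1.0])

    def test_matches_per_base_oracle(self, rng):
        starts = np.sort(rng.choice(np.arange(0, 199_900, 100), size=60, replace=False))
        records = [("chr1", int(s), int(s) + 80, float(rng.uniform(0, 5))) for s in starts]
        track = SignalTrack.from_records(records)
        dense = np.zeros(200_000)
        for _, s, e, v in records:
            dense[s:e] = v
        elements = [iv(int(c)) for c in rng.integers(500, 199_000, size=100)]
        maxima = np.array([dense[e.start : e.end].max() for e in elements])
        expected = (maxima - maxima.mean()) / maxima.std()
        assert compute_max_z(elements, track) == pytest.approx(expected)


class TestClassifyElement:
    def test_promoter_like_signature(self):
        # center 150 bp from the TSS, DNase and H3K4me3 high
        got = classify_element(iv(10_150), AssaySignals(3, 3, 0), TSS)
        assert got is CcreClass.PLS

    def test_proximal_enhancer_within_two_kb(self):
        got = classify_element(iv(11_500), AssaySignals(3, -1, 3), TSS)
        assert got is CcreClass.PELS

    def test_distal_enhancer_beyond_two_kb(self):
        got = classify_element(iv(60_000), AssaySignals(3, -1, 3), TSS)
        assert got is CcreClass.DELS

    def test_dnase_h3k4me3_away_from_tss(self):
        got = classify_element(iv(60_000), AssaySignals(3, 3, -1), TSS)
        assert got is CcreClass.DNASE_H3K4ME3

    def test_dnase_only_and_unclassified(self):
        assert classify_element(iv(60_000), AssaySignals(3, -1, -1), TSS) is CcreClass.DNASE_ONLY
        assert classify_element(iv(60_000), AssaySignals(-1, -1, -1), TSS) is CcreClass.UNCLASSIFIED

    def test_total_function_over_signal_grid(self):
        # every combination of high/low signals and distances yields exactly one class
        for d, center in ((100, 10_100), (1500, 11_500), (50_000, 60_000)):
            for dn in (-1, 3):
                for k4 in (-1, 3):
                    for k27 in (-1, 3):
                        got = classify_element(iv(center), AssaySignals(dn, k4, k27), TSS)
                        assert isinstance(got, CcreClass)

    def test_raising_high_z_only_shrinks_classified_set(self):
        sig = AssaySignals(2.0, 2.0, 0.0)
        lenient = classify_element(iv(10_100), sig, TSS, CcreParams(high_z=1.64, low_z=1.64))
        strict = classify_element(iv(10_100), sig, TSS, CcreParams(high_z=2.5, low_z=2.5))
        assert lenient is CcreClass.PLS
        assert strict is CcreClass.UNCLASSIFIED


class TestPeakDistribution:
    def catalog(self):
        return [
            CcreRecord(iv(10_100), AssaySignals(3, 3, 0), CcreClass.PLS),
            CcreRecord(iv(60_000), AssaySignals(3, -1, 3), CcreClass.DELS),
        ]

    def test_all_peaks_in_promoter_elements(self):
        peaks = [Peak(iv(10_100), name="a"), Peak(iv(10_120), name="b")]
        _, fracs = peakset_class_distribution(peaks, self.catalog())
        assert fracs[CcreClass.PLS] == 1.0

    def test_no_overlap_means_unclassified(self):
        peaks = [Peak(iv(500_000), name="a")]
        _, fracs = peakset_class_distribution(peaks, self.catalog())
        assert fracs[CcreClass.UNCLASSIFIED] == 1.0

    def test_largest_overlap_wins(self):
        catalog = [
            CcreRecord(GenomicInterval("chr1", 0, 100), ccre_class=CcreClass.PLS),
            CcreRecord(GenomicInterval("chr1", 80, 400), ccre_class=CcreClass.DELS),
        ]
        peaks = [Peak(GenomicInterval("chr1", 50, 350), name="p")]
        classes = assign_peak_classes(peaks, catalog)
        assert classes["p"] is CcreClass.DELS

    def test_fractions_sum_to_one(self, annotation, sim_config, rng):
        peaks, _ = simulate_target_peaks(sim_config, annotation, rng)
        _, fracs = peakset_class_distribution(peaks, annotation.catalog)
        assert sum(fracs.values()) == pytest.approx(1.0, abs=1e-9)

    def test_planted_fractions_recovered(self, annotation, sim_config, rng):
        peaks, truth = simulate_target_peaks(sim_config, annotation, rng)
        classes, fracs = peakset_class_distribution(peaks, annotation.catalog)
        assert classes == truth
        assert fracs[CcreClass.PLS] == pytest.approx(0.48, abs=0.02)
        assert fracs[CcreClass.PELS] == pytest.approx(0.134, abs=0.02)
        assert fracs[CcreClass.DELS] == pytest.approx(0.097, abs=0.02)


class TestSignalMatrix:
    def test_constant_track_fills_matrix(self):
        track = SignalTrack.from_records([("chr1", 0, 100_000, 2.5)])
        peaks = [Peak(iv(10_000, 200), name="a"), Peak(iv(50_000, 200), name="b")]
        mat, order = signal_matrix(peaks, track, flank_bp=2500, bin_bp=50)
        assert mat.shape == (2, 100)
        assert np.all(mat == 2.5)

    def test_rectangular_block_matches_hand_binning(self):
        # block of value 4.0 covering [9975, 10025): straddles the center
        track = SignalTrack.from_records([("chr1", 9975, 10_025, 4.0)])
        peaks = [Peak(iv(10_000, 200), name="a")]
        mat, _ = signal_matrix(peaks, track, flank_bp=100, bin_bp=50)
        # bins: [9900,9950) 0; [9950,10000) half covered; [10000,10050) half; [10050,10100) 0
        assert mat[0] == pytest.approx([0.0, 2.0, 2.0, 0.0])

    def test_out_of_chromosome_bins_are_absent_not_zero(self):
        genome = Genome({"chr1": 10_050})
        track = SignalTrack.from_records([("chr1", 0, 10_050, 1.0)])
        peaks = [Peak(iv(10_000, 100), name="edge")]
        mat, _ = signal_matrix(peaks, track, flank_bp=100, bin_bp=50, genome=genome)
        assert np.isnan(mat[0, -1]) and mat[0, 0] == 1.0

    def test_rows_sorted_by_descending_mean(self):
        track = SignalTrack.from_records([("chr1", 0, 20_000, 1.0), ("chr1", 40_000, 60_000, 9.0)])
        peaks = [Peak(iv(10_000, 200), name="lo"), Peak(iv(50_000, 200), name="hi")]
        mat, order = signal_matrix(peaks, track, flank_bp=500, bin_bp=50)
        assert order == [1, 0]
        assert mat[0].mean() > mat[1].mean()
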