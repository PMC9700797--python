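import numpy as np
import pandas as pd
import pytest

from epimem.annotation import GeneAnnotation, GenomicInterval
from epimem.chip_quant import (
    QuantifiedPeak,
    background_adjust,
    count_reads_in_intervals,
    coverage_track,
    gene_score_matrix,
    gene_tss_score,
    quantify_peaks,
    read_library_manifest,
    read_peaks,
    read_reads_bed,
    rpkm,
    write_intervals_bed,
)


def brute_force_counts(reads, targets, min_overlap=1):
    """Independent O(n*m) oracle over all (read, target) pairs."""
    counts = []
    for t in targets:
        c = 0
        for r in reads:
            if r.chrom == t.chrom and min(r.end, t.end) - max(r.start, t.start) >= min_overlap:
                c += 1
        counts.append(c)
    return np.array(counts)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=100_000, min_len=20, max_len=400):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(min_len, max_len))
        out.append(GenomicInterval(str(rng.choice(chroms)), start, start + length))
    return out


class TestCounting:
    def test_both_reads_overlap_single_target(self):
        reads = [GenomicInterval("chr1", 100, 150), GenomicInterval("chr1", 200, 250)]
        target = [GenomicInterval("chr1", 140, 210)]
        assert count_reads_in_intervals(reads, target).tolist() == [2]

    def test_half_open_abutment_does_not_count(self):
        reads = [GenomicInterval("chr1", 100, 150)]
        target = [GenomicInterval("chr1", 150, 200)]
        assert count_reads_in_intervals(reads, target).tolist() == [0]

    @pytest.mark.parametrize("min_overlap", [1, 25])
    def test_matches_nested_loop_oracle(self, rng, min_overlap):
        reads = random_intervals(rng, 1000, min_len=50, max_len=51)
        targets = random_intervals(rng, 20, min_len=100, max_len=5000)
        got = count_reads_in_intervals(reads, targets, min_overlap_bp=min_overlap)
        assert got.tolist() == brute_force_counts(reads, targets, min_overlap).tolist()

    def test_dataframe_reads_equal_interval_reads(self, rng):
        reads = random_intervals(rng, 300)
        df = pd.DataFrame(
            {"chrom": [r.chrom for r in reads],
             "start": [r.start for r in reads],
             "end": [r.end for r in reads]}
        )
        targets = random_intervals(rng, 10, min_len=500, max_len=2000)
        assert (
            count_reads_in_intervals(df, targets).tolist()
            == count_reads_in_intervals(reads, targets).tolist()
        )

    def test_empty_inputs_give_zeros(self):
        t = [GenomicInterval("chr1", 0, 10)]
        assert count_reads_in_intervals([], t).tolist() == [0]
        assert count_reads_in_intervals(t, []).tolist() == []


class TestRpkm:
    def test_formula_fixture(self):
        assert rpkm(100, 1000, 10_000_000) == 10.0

    def test_zero_count(self):
        assert rpkm(0, 500, 1_000_000) == 0.0

    def test_arithmetic_oracle(self):
        # spreadsheet-style: 37 / ((1234/1000) * (8.4e6/1e6))
        expected = 37 / (1.234 * 8.4)
        assert rpkm(37, 1234, 8_400_000) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance(self):
        base = rpkm(100, 1000, 10_000_000)
        assert rpkm(200, 1000, 20_000_000) == pytest.approx(base, rel=1e-12)

    @pytest.mark.parametrize("length,lib", [(0, 1), (10, 0), (-5, 100)])
    def test_invalid_inputs_error(self, length, lib):
        with pytest.raises(ValueError):
            rpkm(1, length, lib)


def make_peak(chrom="chr1", start=0, end=1000, chip_rpkm=1.0, input_rpkm=0.0):
    return QuantifiedPeak(
        interval=GenomicInterval(chrom, start, end),
        mark="H3K4me3",
        sample_id="s1",
        chip_count=1,
        input_count=0,
        chip_rpkm=chip_rpkm,
        input_rpkm=input_rpkm,
        adjusted_rpkm=chip_rpkm - input_rpkm,
    )


class TestBackgroundAdjust:
    def test_subtraction_and_exclusion_rules(self):
        peaks = [
            make_peak(start=0, end=1000, chip_rpkm=10, input_rpkm=3),
            make_peak(start=2000, end=3000, chip_rpkm=2, input_rpkm=2),
            make_peak(start=4000, end=5000, chip_rpkm=1, input_rpkm=4),
        ]
        retained, dropped = background_adjust(peaks)
        assert dropped == 2
        assert len(retained) == 1
        assert retained[0].adjusted_rpkm == pytest.approx(7.0)

    def test_idempotent_on_own_output(self, rng):
        peaks = [
            make_peak(start=i * 1000, end=i * 1000 + 500,
                      chip_rpkm=float(c), input_rpkm=float(b))
            for i, (c, b) in enumerate(zip(rng.uniform(0, 5, 50), rng.uniform(0, 5, 50)))
        ]
        once, _ = background_adjust(peaks)
        twice, dropped = background_adjust(once)
        assert dropped == 0
        assert twice == once

    def test_order_preserved(self):
        peaks = [make_peak(start=s, end=s + 100, chip_rpkm=5, input_rpkm=1)
                 for s in (5000, 1000, 3000)]
        retained, _ = background_adjust(peaks)
        assert [p.interval.start for p in retained] == [5000, 1000, 3000]


class TestGeneTssScore:
    def test_mean_of_overlapping_peaks(self, plus_gene):
        peaks = [
            make_peak(start=9_000, end=9_500, chip_rpkm=4.0),
            make_peak(start=11_000, end=11_500, chip_rpkm=6.0),
            make_peak(start=50_000, end=50_500, chip_rpkm=99.0),
        ]
        score = gene_tss_score(peaks, plus_gene)
        assert score.score == pytest.approx(5.0)
        assert score.n_support == 2

    def test_no_overlap_gives_missing(self, plus_gene):
        peaks = [make_peak(start=50_000, end=50_500)]
        score = gene_tss_score(peaks, plus_gene)
        assert score.n_support == 0
        assert np.isnan(score.score)

    def test_permutation_invariant(self, rng, plus_gene):
        peaks = [
            make_peak(start=int(s), end=int(s) + 300, chip_rpkm=float(v))
            for s, v in zip(rng.integers(7000, 13000, 20), rng.uniform(1, 9, 20))
        ]
        a = gene_tss_score(peaks, plus_gene).score
        shuffled = [peaks[i] for i in rng.permutation(20)]
        b = gene_tss_score(shuffled, plus_gene).score
        assert a == pytest.approx(b, rel=1e-12)

    def test_matches_brute_force_recomputation(self, rng):
        genes = [
            GeneAnnotation.from_body(f"g{i}", f"g{i}", "chr1", str(s), int(t), int(t) + 100)
            if s == "+"
            else GeneAnnotation.from_body(f"g{i}", f"g{i}", "chr1", "-", int(t) - 99, int(t) + 1)
            for i, (t, s) in enumerate(
                zip(rng.integers(5000, 95_000, 10), rng.choice(["+", "-"], 10))
            )
        ]
        peaks = [
            make_peak(start=int(s), end=int(s) + int(w), chip_rpkm=float(v))
            for s, w, v in zip(
                rng.integers(0, 100_000, 50),
                rng.integers(200, 2000, 50),
                rng.uniform(0.5, 20, 50),
            )
        ]
        for g in genes:
            # first-principles oracle: strand-oriented window, inclusive overlap
            if g.strand == "+":
                lo, hi = g.tss - 2000, g.tss + 3000
            else:
                lo, hi = g.tss - 3000, g.tss + 2000
            lo = max(lo, 0)
            vals = [
                p.adjusted_rpkm
                for p in peaks
                if min(p.interval.end, hi) - max(p.interval.start, lo) >= 1
            ]
            got = gene_tss_score(peaks, g)
            assert got.n_support == len(vals)
            if vals:
                assert got.score == pytest.approx(sum(vals) / len(vals), rel=1e-12)

    def test_matrix_agrees_with_scalar_path(self, rng, plus_gene, minus_gene):
        peaks = [
            make_peak(start=int(s), end=int(s) + 400, chip_rpkm=float(v))
            for s, v in zip(rng.integers(5000, 15000, 30), rng.uniform(1, 5, 30))
        ]
        genes = [plus_gene, minus_gene]
        mat = gene_score_matrix({"s1": peaks}, genes)
        for g in genes:
            expect = gene_tss_score(peaks, g).score
            got = mat.loc[g.gene_id, "s1"]
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, rel=1e-12)

    def test_zero_fill_option(self, plus_gene):
        mat = gene_score_matrix({"s1": []}, [plus_gene], zero_fill=True)
        assert mat.loc["GeneA", "s1"] == 0.0


class TestQuantifyPeaks:
    def test_counts_and_rpkm_pair(self):
        peaks = [GenomicInterval("chr1", 0, 1000)]
        chip = [GenomicInterval("chr1", 10, 60)] * 0 + [
            GenomicInterval("chr1", i * 10, i * 10 + 50) for i in range(10)
        ]
        inp = [GenomicInterval("chr1", 0, 50)]
        (q,) = quantify_peaks(peaks, chip, inp, 1_000_000, 2_000_000, "H3K4me3", "s")
        assert q.chip_count == 10 and q.input_count == 1
        assert q.chip_rpkm == pytest.approx(10.0)
        assert q.input_rpkm == pytest.approx(0.5)
        assert q.adjusted_rpkm == pytest.approx(9.5)


class TestCoverageTrack:
    def test_rpm_formula(self):
        reads = [GenomicInterval("chr1", 100, 150)] * 5
        track = coverage_track(reads, GenomicInterval("chr1", 0, 200), 200, 5_000_000)
        assert track["rpm"].tolist() == [1.0]

    def test_empty_region_all_zero(self):
        track = coverage_track([], GenomicInterval("chr1", 0, 1000), 100, 1_000_000)
        assert (track["rpm"] == 0).all()
        assert len(track) == 10

    def test_last_bin_short(self):
        track = coverage_track([], GenomicInterval("chr1", 0, 250), 100, 1_000_000)
        assert track[["start", "end"]].to_numpy().tolist() == [[0, 100], [100, 200], [200, 250]]

    def test_matches_nested_loop_oracle(self, rng):
        reads = random_intervals(rng, 500, chroms=("chr1",), span=10_000, min_len=50, max_len=51)
        region = GenomicInterval("chr1", 2000, 8000)
        lib = 3_000_000
        track = coverage_track(reads, region, 300, lib)
        for row in track.itertuples(index=False):
            c = sum(
                1 for r in reads if min(r.end, row.end) - max(r.start, row.start) >= 1
            )
            assert row.rpm == pytest.approx(c / (lib / 1e6), rel=1e-12)


class TestReaders:
    def test_read_peaks_accepts_narrowpeak_extras(self, tmp_path):
        p = tmp_path / "p.narrowPeak"
        p.write_text("chr1\t100\t600\tpeak1\t800\t.\t5.2\t12.1\t10.3\t250\n")
        (peak,) = read_peaks(p)
        assert (peak.chrom, peak.start, peak.end) == ("chr1", 100, 600)

    def test_read_reads_roundtrip(self, tmp_path, rng):
        intervals = random_intervals(rng, 100)
        p = tmp_path / "r.bed"
        write_intervals_bed(intervals, p)
        df = read_reads_bed(p)
        assert len(df) == 100
        assert df["start"].tolist() == [iv.start for iv in intervals]

    def test_manifest_rejects_unknown_mark(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text(
            "sample_id\tgroup\tmark\tlibrary_size\n"
            "s1\tPTC\tH3K9me3\t1000000\n"
        )
        with pytest.raises(ValueError, match="unknown marks"):
            read_library_manifest(p)
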