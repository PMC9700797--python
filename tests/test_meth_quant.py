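import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epimem.meth_quant import (
    MethSiteRecord,
    center_and_average,
    gene_meth_score,
    meth_score_matrix,
    read_methylation_frequency,
    site_frequency,
    sliding_windows,
    tss_meth_profile,
    write_methylation_frequency,
)


def sites_frame(rows):
    """rows: (chrom, start, called, methylated)"""
    df = pd.DataFrame(rows, columns=["chromosome", "start", "called_sites", "called_sites_methylated"])
    df["end"] = df["start"] + 1
    df["num_motifs_in_group"] = 1
    df["methylated_frequency"] = df["called_sites_methylated"] / df["called_sites"]
    df["group_sequence"] = "CG"
    return df


class TestMethSiteRecord:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            MethSiteRecord("chr1", 10, 11, 1, 5, 6, 1.2)
        with pytest.raises(ValueError):
            MethSiteRecord("chr1", 10, 11, 1, 10, 4, 0.9)
        rec = MethSiteRecord("chr1", 10, 11, 1, 10, 4, 0.4)
        assert rec.methylated_frequency == 0.4


class TestSiteFrequency:
    def test_simple_ratio_and_bounds(self):
        calls = pd.DataFrame(
            {
                "chromosome": ["chr1"] * 20,
                "start": [100] * 10 + [200] * 5 + [300] * 5,
                "end": [101] * 10 + [201] * 5 + [301] * 5,
                "read_name": [f"r{i}" for i in range(20)],
                "methylated": [True] * 4 + [False] * 6 + [False] * 5 + [True] * 5,
            }
        )
        out = site_frequency(calls).set_index("start")
        assert out.loc[100, "methylated_frequency"] == pytest.approx(0.4)
        assert out.loc[200, "methylated_frequency"] == 0.0
        assert out.loc[300, "methylated_frequency"] == 1.0

    def test_matches_brute_force_tally(self, rng):
        sites = rng.integers(0, 20, size=200) * 50
        meth = rng.random(200) < 0.3
        calls = pd.DataFrame(
            {
                "chromosome": "chr1",
                "start": sites,
                "end": sites + 1,
                "read_name": [f"r{i}" for i in range(200)],
                "methylated": meth,
            }
        )
        out = site_frequency(calls).set_index("start")
        for s in np.unique(sites):
            m = meth[sites == s]
            assert out.loc[s, "called_sites"] == len(m)
            assert out.loc[s, "methylated_frequency"] == pytest.approx(m.mean())

    def test_llr_threshold_drops_ambiguous_calls(self):
        calls = pd.DataFrame(
            {
                "chromosome": ["chr1"] * 4,
                "start": [100] * 4,
                "end": [101] * 4,
                "read_name": list("abcd"),
                "log_lik_ratio": [3.0, -3.0, 0.5, -0.5],
            }
        )
        out = site_frequency(calls, llr_threshold=2.0)
        assert out.loc[0, "called_sites"] == 2
        assert out.loc[0, "methylated_frequency"] == pytest.approx(0.5)


class TestSlidingWindows:
    def test_default_gives_57_windows(self):
        w = sliding_windows(2000, 300, 30)
        assert len(w) == 57
        assert w[0] == -1000 and w[-1] == 680

    def test_window_equal_region_is_single(self):
        assert sliding_windows(2000, 2000, 30).tolist() == [-1000]

    def test_step_equal_window_tiles(self):
        assert len(sliding_windows(2000, 300, 300)) == 6

    def test_window_larger_than_region_errors(self):
        with pytest.raises(ValueError):
            sliding_windows(200, 300, 30)


class TestTssMethProfile:
    def test_pooled_fraction(self, plus_gene):
        # two sites in the same windows: (3/10 + 1/10) pooled = 4/20
        sites = sites_frame(
            [("chr1", 10_050, 10, 3), ("chr1", 10_060, 10, 1)]
        )
        prof = tss_meth_profile(sites, plus_gene)
        idx = np.flatnonzero(~np.isnan(prof.window_fractions))
        assert len(idx) > 0
        for i in idx:
            assert prof.window_fractions[i] == pytest.approx(0.2)

    def test_per_site_average_mode_differs(self, plus_gene):
        sites = sites_frame([("chr1", 10_050, 100, 50), ("chr1", 10_060, 10, 0)])
        pooled = tss_meth_profile(sites, plus_gene, pooled=True)
        avg = tss_meth_profile(sites, plus_gene, pooled=False)
        i = np.flatnonzero(~np.isnan(pooled.window_fractions))[0]
        assert pooled.window_fractions[i] == pytest.approx(50 / 110)
        assert avg.window_fractions[i] == pytest.approx(0.25)

    def test_empty_windows_are_missing(self, plus_gene):
        sites = sites_frame([("chr2", 10_050, 10, 5)])  # wrong chromosome
        prof = tss_meth_profile(sites, plus_gene)
        assert np.isnan(prof.window_fractions).all()
        assert (prof.n_cpg_per_window == 0).all()

    def test_strand_aware_offsets_mirror(self, minus_gene):
        # minus gene TSS at 10_000; a site 500 bp genomic-left is +500 downstream
        sites = sites_frame([("chr1", 9_500, 10, 10)])
        prof = tss_meth_profile(sites, minus_gene)
        covered = prof.window_starts[~np.isnan(prof.window_fractions)]
        assert covered.min() >= 500 - 300 and covered.max() <= 500

    def test_matches_brute_force_pooling(self, rng, plus_gene):
        pos = rng.integers(8_500, 11_500, 80)
        called = rng.integers(1, 40, 80)
        meth = rng.binomial(called, 0.4)
        sites = sites_frame(
            [("chr1", int(p), int(c), int(m)) for p, c, m in zip(pos, called, meth)]
        )
        prof = tss_meth_profile(sites, plus_gene)
        for w, f in zip(prof.window_starts, prof.window_fractions):
            sel = (pos - plus_gene.tss >= w) & (pos - plus_gene.tss < w + 300)
            if sel.sum() == 0:
                assert np.isnan(f)
            else:
                assert f == pytest.approx(meth[sel].sum() / called[sel].sum(), rel=1e-12)

    def test_single_cpg_tiling_reduces_to_site_frequency(self, plus_gene):
        # one CpG per non-overlapping window: window fraction == site frequency
        sites = sites_frame(
            [("chr1", plus_gene.tss - 1000 + 300 * i + 150, 10, i) for i in range(6)]
        )
        prof = tss_meth_profile(sites, plus_gene, window=300, step=300)
        assert np.allclose(prof.window_fractions, [i / 10 for i in range(6)])


class TestGeneMethScore:
    def test_reductions(self, plus_gene):
        sites = sites_frame([("chr1", 9_100, 10, 2), ("chr1", 10_900, 10, 4)])
        prof = tss_meth_profile(sites, plus_gene)
        mean = gene_meth_score(prof, "mean")
        mn = gene_meth_score(prof, "min")
        md = gene_meth_score(prof, "median")
        assert 0.2 <= mean <= 0.4
        assert mn == pytest.approx(0.2)
        assert 0.2 <= md <= 0.4

    def test_all_missing_gives_nan(self, plus_gene):
        sites = sites_frame([("chr2", 100, 5, 1)])
        prof = tss_meth_profile(sites, plus_gene)
        assert np.isnan(gene_meth_score(prof))

    def test_unknown_reduction_errors(self, plus_gene):
        sites = sites_frame([("chr1", 10_000, 5, 1)])
        prof = tss_meth_profile(sites, plus_gene)
        with pytest.raises(ValueError):
            gene_meth_score(prof, "max")


class TestCenterAndAverage:
    def test_mean_removal(self):
        raw = pd.DataFrame({"s1": [0.2, 0.4, 0.6], "s2": [0.5, 0.5, 0.5]},
                           index=["a", "b", "c"])
        centered, _ = center_and_average(raw, [("s1", "s2", "g")])
        assert centered["s1"].tolist() == pytest.approx([-0.2, 0.0, 0.2])
        assert abs(centered.mean(axis=0)).max() < 1e-9

    def test_replicate_mean_of_two(self):
        raw = pd.DataFrame({"s1": [0.1, 0.3], "s2": [0.5, 0.1]}, index=["a", "b"])
        centered, avg = center_and_average(raw, [("s1", "s2", "g")])
        # centered: s1 -> (-0.1, +0.1); s2 -> (+0.2, -0.2)
        assert avg["g"].tolist() == pytest.approx([0.05, -0.05])

    def test_single_replicate_gene_excluded_by_default(self):
        raw = pd.DataFrame({"s1": [0.1, 0.3, 0.2], "s2": [0.4, np.nan, 0.1]},
                           index=["a", "b", "c"])
        _, strict = center_and_average(raw, [("s1", "s2", "g")])
        assert np.isnan(strict.loc["b", "g"])
        _, kept = center_and_average(raw, [("s1", "s2", "g")], keep_single=True)
        assert not np.isnan(kept.loc["b", "g"])

    def test_missing_sample_errors(self):
        raw = pd.DataFrame({"s1": [0.1, 0.2]}, index=["a", "b"])
        with pytest.raises(KeyError):
            center_and_average(raw, [("s1", "nope", "g")])

    @given(shift=st.floats(min_value=-10, max_value=10, allow_nan=False))
    def test_shift_invariance(self, shift):
        raw = pd.DataFrame({"s1": [0.2, 0.5, 0.8], "s2": [0.1, 0.4, 0.9]},
                           index=["a", "b", "c"])
        base, _ = center_and_average(raw, [("s1", "s2", "g")])
        shifted, _ = center_and_average(raw + shift, [("s1", "s2", "g")])
        assert np.allclose(base.to_numpy(), shifted.to_numpy(), atol=1e-9)

    def test_rank_order_preserved(self, rng):
        raw = pd.DataFrame({"s1": rng.random(30), "s2": rng.random(30)})
        centered, _ = center_and_average(raw, [("s1", "s2", "g")])
        assert (np.argsort(raw["s1"].to_numpy()) == np.argsort(centered["s1"].to_numpy())).all()


class TestIO:
    def test_roundtrip(self, tmp_path):
        df = sites_frame([("chr1", 100, 10, 4), ("chr1", 200, 5, 5)])
        p = tmp_path / "m.tsv"
        write_methylation_frequency(df, p)
        back = read_methylation_frequency(p)
        assert back["called_sites_methylated"].tolist() == [4, 5]

    def test_inconsistent_table_rejected(self, tmp_path):
        df = sites_frame([("chr1", 100, 10, 4)])
        df.loc[0, "called_sites_methylated"] = 20
        p = tmp_path / "m.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="exceed"):
            read_methylation_frequency(p)


def test_score_matrix_agrees_with_profile_path(rng, plus_gene, minus_gene):
    pos = rng.integers(7_000, 13_000, 120)
    called = rng.integers(1, 30, 120)
    meth = rng.binomial(called, 0.5)
    sites = sites_frame(
        [("chr1", int(p), int(c), int(m)) for p, c, m in zip(pos, called, meth)]
    )
    genes = [plus_gene, minus_gene]
    mat = meth_score_matrix({"s": sites}, genes)
    for g in genes:
        expect = gene_meth_score(tss_meth_profile(sites, g))
        assert mat.loc[g.gene_id, "s"] == pytest.approx(expect, rel=1e-12)
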