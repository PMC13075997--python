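import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splicechrom.annotation import GeneModel, GenomeSequence, GenomicInterval
from splicechrom.coverage import CoverageTrack, FragmentSet
from splicechrom.occupancy import (
    column_mean_profile,
    count_fragments_in,
    eclip_fold_change,
    feature_occupancy_table,
    feature_rpk,
    gene_rpk,
    log_expression,
    metagene_reference_point,
    metagene_scale_regions,
    nucleosome_occupancy,
    read_metagene,
    write_metagene,
)

from conftest import random_fragments


def brute_force_count(frags: FragmentSet, region):
    n = 0
    for chrom, (starts, ends) in frags.by_chrom.items():
        if chrom != region.chrom:
            continue
        for s, e in zip(starts, ends):
            if s < region.end and region.start < e:
                n += 1
    return n


class TestCountFragments:
    def test_one_bp_overlap_counts(self):
        frags = FragmentSet({"c": (np.array([0]), np.array([10]))})
        assert count_fragments_in(frags, GenomicInterval("c", 9, 20)) == 1

    def test_half_open_abutment_does_not_count(self):
        frags = FragmentSet({"c": (np.array([0]), np.array([10]))})
        assert count_fragments_in(frags, GenomicInterval("c", 10, 20)) == 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        frags = random_fragments(rng, "c", 3000, int(rng.integers(0, 120)))
        region = GenomicInterval(
            "c", int(rng.integers(0, 2900)), int(rng.integers(2901, 3000))
        )
        assert count_fragments_in(frags, region) == brute_force_count(frags, region)


class TestGeneRpk:
    def make_gene(self, start, end):
        return GeneModel(
            "g", GenomicInterval("c", start, end, "+"),
            [GenomicInterval("c", start, end, "+")],
        )

    def test_no_fragments(self):
        rec = gene_rpk(FragmentSet({}), self.make_gene(2000, 4000))
        assert rec.rpk == 0 and rec.density == 0

    def test_flanked_numerator_gene_length_denominator(self):
        # 8 fragments inside the +-1kb flanks of a 2 kb gene -> rpk 4
        gene = self.make_gene(2000, 4000)
        starts = np.array([1500, 1900, 2100, 2500, 3000, 3500, 4200, 4800])
        frags = FragmentSet({"c": (starts, starts + 100)})
        rec = gene_rpk(frags, gene, flank=1000)
        assert rec.fragment_count == 8
        assert rec.rpk == pytest.approx(4.0)
        assert rec.density == pytest.approx(math.log2(5), abs=1e-12)

    def test_density_log2_of_one_plus_rpk(self):
        gene = self.make_gene(1000, 2000)
        starts = np.arange(1000, 2000, 67)[:15]
        frags = FragmentSet({"c": (starts, starts + 10)})
        rec = gene_rpk(frags, gene, flank=0)
        assert rec.rpk == 15.0 and rec.density == 4.0


class TestFeatureRpk:
    def test_exact_span_counts_once(self, simple_gene):
        frags = FragmentSet({"chrA": (np.array([1000]), np.array([1100]))})
        assert feature_rpk(frags, simple_gene, "exon", 1) == pytest.approx(1 / 0.1)

    def test_empty_feature_is_zero(self, simple_gene):
        assert feature_rpk(FragmentSet({}), simple_gene, "intron", 1) == 0.0

    def test_missing_ordinal_raises(self, simple_gene):
        with pytest.raises(IndexError):
            feature_rpk(FragmentSet({}), simple_gene, "exon", 4)

    def test_minus_strand_ordinal_follows_transcription(self, minus_gene):
        # exon 1 of a minus gene is the rightmost exon
        frags = FragmentSet({"chrA": (np.array([3600]), np.array([3640]))})
        assert feature_rpk(frags, minus_gene, "exon", 1) > 0
        assert feature_rpk(frags, minus_gene, "exon", 2) == 0

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force(self, seed):
        gene = GeneModel(
            "g", GenomicInterval("chrA", 1000, 1700, "+"),
            [GenomicInterval("chrA", 1000, 1100, "+"),
             GenomicInterval("chrA", 1300, 1400, "+"),
             GenomicInterval("chrA", 1600, 1700, "+")],
        )
        rng = np.random.default_rng(seed)
        frags = random_fragments(rng, "chrA", 3000, int(rng.integers(1, 150)))
        for ordinal in (1, 2, 3):
            exon = gene.exons[ordinal - 1]
            expected = brute_force_count(frags, exon) / (exon.length / 1000)
            assert feature_rpk(frags, gene, "exon", ordinal) == pytest.approx(expected)


class TestNucleosomeOccupancy:
    def test_length_threshold_inclusive_at_150(self):
        starts = np.array([0, 0, 0])
        ends = np.array([100, 150, 200])
        frags = FragmentSet({"c": (starts, ends)})
        region = GenomicInterval("c", 0, 2000)
        assert nucleosome_occupancy(frags, region, per="kb") == pytest.approx(2 / 2.0)

    def test_per_kb(self):
        starts = np.zeros(4, dtype=int)
        frags = FragmentSet({"c": (starts, starts + 160)})
        assert nucleosome_occupancy(frags, GenomicInterval("c", 0, 2000), per="kb") == 2.0

    def test_per_kgc(self):
        seq = GenomeSequence({"c": "GC" * 250 + "AT" * 750})  # 500 GC bases in 2 kb
        starts = np.zeros(4, dtype=int)
        frags = FragmentSet({"c": (starts, starts + 160)})
        region = GenomicInterval("c", 0, 2000)
        assert nucleosome_occupancy(frags, region, seq, per="kGC") == 8.0

    def test_zero_gc_region_rejected(self):
        seq = GenomeSequence({"c": "AT" * 100})
        frags = FragmentSet({"c": (np.array([0]), np.array([160]))})
        with pytest.raises(ValueError, match="zero GC"):
            nucleosome_occupancy(frags, GenomicInterval("c", 0, 200), seq, per="kGC")


class TestScalars:
    def test_eclip_fold_change(self):
        assert eclip_fold_change(10, 5) == 2.0
        assert eclip_fold_change(7, 7) == 1.0
        assert eclip_fold_change(0, 5) == 0.0
        with pytest.raises(ValueError):
            eclip_fold_change(3, 0)

    def test_log_expression(self):
        assert log_expression(0) == 0.0
        assert log_expression(1) == 1.0
        assert log_expression(3) == 2.0
        with pytest.raises(ValueError):
            log_expression(-1)


def step_track(length, boundary, low=0.0, high=1.0):
    v = np.full(length, low)
    v[boundary:] = high
    return CoverageTrack({"chrA": v}, mode="raw")


class TestMetageneReferencePoint:
    def test_constant_track(self, simple_gene):
        track = CoverageTrack({"chrA": np.full(10_000, 3.0)}, mode="raw")
        m = metagene_reference_point(track, [simple_gene], "TSS", 500, 500, 50)
        assert m.values.shape == (1, 20)
        assert np.all(m.values == 3.0)

    def test_step_at_tss_plus_strand(self, simple_gene):
        track = step_track(10_000, simple_gene.tss)
        m = metagene_reference_point(track, [simple_gene], "TSS", 200, 200, 50)
        assert np.all(m.values[0, :4] == 0) and np.all(m.values[0, 4:] == 1)

    def test_minus_strand_rows_are_flipped(self, minus_gene):
        # signal only downstream (in transcription direction) of the - TSS
        v = np.zeros(10_000)
        v[: minus_gene.tss] = 1.0
        track = CoverageTrack({"chrA": v}, mode="raw")
        m = metagene_reference_point(track, [minus_gene], "TSS", 200, 200, 50)
        assert np.all(m.values[0, :4] == 0) and np.all(m.values[0, 4:] == 1)

    def test_strand_mirror_symmetry(self):
        """A + gene and its mirrored - gene over mirrored coverage give
        identical metagene rows."""
        L = 2000
        rng = np.random.default_rng(5)
        v = rng.random(L)
        plus = GeneModel("p", GenomicInterval("chrA", 800, 1200, "+"),
                         [GenomicInterval("chrA", 800, 1200, "+")])
        minus = GeneModel("m", GenomicInterval("chrA", L - 1200, L - 800, "-"),
                          [GenomicInterval("chrA", L - 1200, L - 800, "-")])
        t_plus = CoverageTrack({"chrA": v}, mode="raw")
        t_minus = CoverageTrack({"chrA": v[::-1].copy()}, mode="raw")
        m_plus = metagene_reference_point(t_plus, [plus], "TSS", 200, 200, 50)
        m_minus = metagene_reference_point(t_minus, [minus], "TSS", 200, 200, 50)
        np.testing.assert_allclose(m_plus.values, m_minus.values)

    def test_off_chromosome_bins_missing(self):
        g = GeneModel("g", GenomicInterval("chrA", 100, 400, "+"),
                      [GenomicInterval("chrA", 100, 400, "+")])
        track = CoverageTrack({"chrA": np.ones(10_000)}, mode="raw")
        m = metagene_reference_point(track, [g], "TSS", 500, 500, 50)
        assert np.isnan(m.values[0, 0]) and m.values[0, -1] == 1.0

    def test_bin_means_match_brute_force(self):
        rng = np.random.default_rng(7)
        v = rng.random(5000)
        track = CoverageTrack({"chrA": v}, mode="raw")
        g = GeneModel("g", GenomicInterval("chrA", 2500, 3000, "+"),
                      [GenomicInterval("chrA", 2500, 3000, "+")])
        m = metagene_reference_point(track, [g], "TSS", 400, 400, 20)
        for j in range(40):
            s = 2100 + j * 20
            assert m.values[0, j] == pytest.approx(v[s : s + 20].mean())


class TestMetageneScaleRegions:
    def test_constant_track_constant_matrix(self, simple_gene, minus_gene):
        track = CoverageTrack({"chrA": np.full(10_000, 2.5)}, mode="raw")
        m = metagene_scale_regions(track, [simple_gene, minus_gene], 200, 200, 10, 50)
        assert np.all(m.values == 2.5)

    def test_length_invariance(self):
        track = CoverageTrack({"chrA": np.full(10_000, 1.5)}, mode="raw")
        g1 = GeneModel("a", GenomicInterval("chrA", 1000, 2000, "+"),
                       [GenomicInterval("chrA", 1000, 2000, "+")])
        g2 = GeneModel("b", GenomicInterval("chrA", 4000, 7000, "+"),
                       [GenomicInterval("chrA", 4000, 7000, "+")])
        m = metagene_scale_regions(track, [g1, g2], 200, 200, 25, 50)
        np.testing.assert_allclose(m.values[0], m.values[1])

    def test_bin_means_match_brute_force_on_piecewise_track(self):
        rng = np.random.default_rng(8)
        v = np.repeat(rng.random(100), 50)  # piecewise-constant, length 5000
        track = CoverageTrack({"chrA": v}, mode="raw")
        g = GeneModel("g", GenomicInterval("chrA", 1000, 2037, "+"),
                      [GenomicInterval("chrA", 1000, 2037, "+")])
        body_bins = 10
        m = metagene_scale_regions(track, [g], 0, 0, body_bins, 50)
        # remainder 7 spread over the leftmost bins: sizes 104 x7 then 103 x3
        sizes = [104] * 7 + [103] * 3
        pos = 1000
        for j, size in enumerate(sizes):
            assert m.values[0, j] == pytest.approx(v[pos : pos + size].mean())
            pos += size

    def test_short_genes_dropped_and_recorded(self):
        track = CoverageTrack({"chrA": np.ones(1000)}, mode="raw")
        short = GeneModel("s", GenomicInterval("chrA", 10, 60, "+"),
                          [GenomicInterval("chrA", 10, 60, "+")])
        ok = GeneModel("k", GenomicInterval("chrA", 100, 400, "+"),
                       [GenomicInterval("chrA", 100, 400, "+")])
        m = metagene_scale_regions(track, [short, ok], 0, 0, 100, 50)
        assert m.gene_ids == ["k"] and m.dropped_genes == ["s"]

    def test_gene_order_invariance(self, simple_gene, minus_gene):
        rng = np.random.default_rng(9)
        track = CoverageTrack({"chrA": rng.random(10_000)}, mode="raw")
        m1 = metagene_scale_regions(track, [simple_gene, minus_gene], 200, 200, 20, 50)
        m2 = metagene_scale_regions(track, [minus_gene, simple_gene], 200, 200, 20, 50)
        np.testing.assert_allclose(
            m1.values[[m1.gene_ids.index("g1"), m1.gene_ids.index("g2")]],
            m2.values[[m2.gene_ids.index("g1"), m2.gene_ids.index("g2")]],
        )


class TestColumnMeanProfile:
    def test_single_row_identity(self, simple_gene):
        track = CoverageTrack({"chrA": np.arange(10_000, dtype=float)}, mode="raw")
        m = metagene_reference_point(track, [simple_gene], "TSS", 200, 200, 50)
        np.testing.assert_allclose(column_mean_profile(m), m.values[0])

    def test_two_rows_average(self, simple_gene, minus_gene):
        track = CoverageTrack({"chrA": np.zeros(10_000)}, mode="raw")
        m = metagene_reference_point(track, [simple_gene, minus_gene], "TSS", 200, 200, 50)
        m.values[0, :] = 0.0
        m.values[1, :] = 2.0
        np.testing.assert_allclose(column_mean_profile(m), 1.0)

    def test_missing_cells_excluded(self, simple_gene):
        track = CoverageTrack({"chrA": np.ones(10_000)}, mode="raw")
        m = metagene_reference_point(track, [simple_gene], "TSS", 200, 200, 50)
        m.values[0, 0] = np.nan
        profile = column_mean_profile(m)
        assert np.isnan(profile[0]) and profile[1] == 1.0


class TestMetageneIO:
    def test_round_trip(self, tmp_path, simple_gene, minus_gene):
        rng = np.random.default_rng(10)
        track = CoverageTrack({"chrA": rng.random(10_000)}, mode="raw")
        m = metagene_scale_regions(track, [simple_gene, minus_gene], 200, 200, 20, 50)
        p = tmp_path / "m.tsv.gz"
        write_metagene(m, p)
        again = read_metagene(p)
        assert again.gene_ids == m.gene_ids and again.anchor == m.anchor
        np.testing.assert_allclose(again.values, m.values, rtol=1e-5)


class TestFeatureTable:
    def test_ordinals_contiguous_and_metrics_consistent(self, toy_genome, simple_gene):
        rng = np.random.default_rng(12)
        frags = random_fragments(rng, "chrA", 10_000, 500)
        table = feature_occupancy_table(frags, frags, [simple_gene], toy_genome)
        exons = table[table["feature"] == "exon"]
        introns = table[table["feature"] == "intron"]
        assert exons["ordinal"].tolist() == [1, 2, 3]
        assert introns["ordinal"].tolist() == [1, 2]
        for _, row in table.iterrows():
            assert row["rpk"] >= 0 and 0 <= row["gc_percent"] <= 100
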