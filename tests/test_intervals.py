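"""Interval model, BED I/O, and set-operation correctness."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from zinchrom.intervals import (
    GeneAnnotation,
    GenomicInterval,
    RegionSet,
    annotate_regions,
    intersect_fraction,
    merge_regions,
    promoter_interval,
    read_bed,
    region_center,
    subtract_blacklist,
    write_bed,
)

from oracles import intersect_fraction_oracle, merge_oracle, subtract_oracle


def random_region_set(rng, n, span=5000, max_len=300, chroms=("chr1", "chr2")):
    ivs = []
    for i in range(n):
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, max_len))
        ivs.append(
            GenomicInterval(str(rng.choice(chroms)), start, start + length, f"iv{i}")
        )
    return RegionSet(ivs)


interval_st = st.builds(
    lambda chrom, start, length: GenomicInterval(chrom, start, start + length),
    chrom=st.sampled_from(["chr1", "chr2"]),
    start=st.integers(0, 2000),
    length=st.integers(1, 300),
)
region_set_st = st.lists(interval_st, min_size=0, max_size=30).map(RegionSet)


class TestGenomicInterval:
    def test_invariants_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 5, strand="x")

    @pytest.mark.parametrize(
        "start,end,center", [(100, 200, 150), (0, 1, 0), (10, 13, 11)]
    )
    def test_region_center_floor_convention(self, start, end, center):
        assert region_center(GenomicInterval("chr1", start, end)) == center


class TestBedIO:
    def test_minimal_bed3_line(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\n")
        rs = read_bed(p)
        assert len(rs) == 1
        assert (rs[0].chrom, rs[0].start, rs[0].end) == ("chr1", 100, 200)

    def test_roundtrip_many_random_intervals(self, rng, tmp_path):
        rs = random_region_set(rng, 1000)
        p = tmp_path / "r.bed"
        write_bed(rs, p)
        assert read_bed(p) == rs

    def test_inverted_coordinates_rejected_with_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\nchr1\t200\t100\n")
        with pytest.raises(ValueError, match="bad.bed:2"):
            read_bed(p)

    def test_too_few_columns_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\n")
        with pytest.raises(ValueError, match=">=3 columns"):
            read_bed(p)


class TestMerge:
    def test_overlapping_pair_coalesces(self):
        a = RegionSet([GenomicInterval("chr1", 0, 10)])
        b = RegionSet([GenomicInterval("chr1", 5, 15)])
        merged = merge_regions([a, b])
        assert [(iv.start, iv.end) for iv in merged] == [(0, 15)]

    def test_bookended_intervals_merge(self):
        s = RegionSet(
            [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 10, 20)]
        )
        assert [(iv.start, iv.end) for iv in merge_regions([s])] == [(0, 20)]

    def test_disjoint_inputs_concatenate_sorted(self):
        a = RegionSet([GenomicInterval("chr2", 50, 60)])
        b = RegionSet([GenomicInterval("chr1", 0, 10)])
        merged = merge_regions([a, b])
        assert [(iv.chrom, iv.start, iv.end) for iv in merged] == [
            ("chr1", 0, 10),
            ("chr2", 50, 60),
        ]

    @given(sets=st.lists(region_set_st, min_size=1, max_size=3))
    def test_matches_coverage_oracle(self, sets):
        merged = merge_regions(sets)
        assert {
            (iv.chrom, iv.start, iv.end) for iv in merged
        } == merge_oracle(sets)

    @given(s=region_set_st)
    def test_idempotent(self, s):
        once = merge_regions([s])
        assert merge_regions([once]) == RegionSet(list(once))


class TestSubtractBlacklist:
    def test_any_overlap_removes_whole_region(self):
        regions = RegionSet([GenomicInterval("chr1", 100, 200)])
        bl = RegionSet([GenomicInterval("chr1", 150, 160)])
        assert len(subtract_blacklist(regions, bl)) == 0

    def test_empty_blacklist_is_identity(self, rng):
        rs = random_region_set(rng, 50)
        assert subtract_blacklist(rs, RegionSet([])) == rs

    @given(a=region_set_st, b=region_set_st)
    def test_matches_all_pairs_oracle(self, a, b):
        assert subtract_blacklist(a, b) == subtract_oracle(a, b)

    @given(s=region_set_st)
    def test_self_subtraction_empty(self, s):
        assert len(subtract_blacklist(s, s)) == 0


class TestIntersectFraction:
    def test_half_overlap_retained(self):
        a = RegionSet([GenomicInterval("chr1", 100, 200)])
        b = RegionSet([GenomicInterval("chr1", 150, 300)])
        assert len(intersect_fraction(a, b, 0.5)) == 1

    def test_forty_percent_overlap_dropped(self):
        a = RegionSet([GenomicInterval("chr1", 100, 200)])
        b = RegionSet([GenomicInterval("chr1", 160, 300)])
        assert len(intersect_fraction(a, b, 0.5)) == 0

    def test_tiny_fraction_keeps_single_bp_overlap(self):
        a = RegionSet([GenomicInterval("chr1", 100, 200)])
        b = RegionSet([GenomicInterval("chr1", 199, 300)])
        assert len(intersect_fraction(a, b, 1e-9)) == 1

    def test_union_of_b_not_double_counted(self):
        a = RegionSet([GenomicInterval("chr1", 100, 200)])
        b = RegionSet(
            [GenomicInterval("chr1", 120, 150), GenomicInterval("chr1", 130, 160)]
        )
        # union covers 40 bp -> below half
        assert len(intersect_fraction(a, b, 0.5)) == 0
        assert len(intersect_fraction(a, b, 0.4)) == 1

    @given(a=region_set_st, b=region_set_st, frac=st.floats(0.05, 1.0))
    def test_matches_bitmap_oracle(self, a, b, frac):
        assert intersect_fraction(a, b, frac) == intersect_fraction_oracle(
            a, b, frac
        )

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            intersect_fraction(RegionSet([]), RegionSet([]), 0.0)


class TestAnnotate:
    genes = [
        GeneAnnotation("gplus", "chr1", 5000, 9000, "+"),
        GeneAnnotation("gminus", "chr2", 1000, 4000, "-"),
    ]

    def test_plus_strand_promoter_upstream_of_tss(self):
        regions = RegionSet([GenomicInterval("chr1", 4500, 4800, "r")])
        assert annotate_regions(regions, self.genes)["r"] == "promoter"

    def test_minus_strand_promoter_downstream_of_tx_end(self):
        regions = RegionSet([GenomicInterval("chr2", 4100, 4200, "r")])
        assert annotate_regions(regions, self.genes)["r"] == "promoter"

    def test_gene_body_without_promoter_overlap_is_genic(self):
        regions = RegionSet([GenomicInterval("chr1", 6000, 6100, "r")])
        assert annotate_regions(regions, self.genes)["r"] == "genic"

    def test_chrom_without_genes_is_nongenic(self):
        regions = RegionSet([GenomicInterval("chr3", 0, 100, "r")])
        assert annotate_regions(regions, self.genes)["r"] == "nongenic"

    def test_promoter_takes_precedence_over_genic(self):
        # region overlaps both the promoter of one gene and the body of another
        genes = [
            GeneAnnotation("a", "chr1", 5000, 9000, "+"),
            GeneAnnotation("b", "chr1", 4000, 4700, "+"),
        ]
        regions = RegionSet([GenomicInterval("chr1", 4500, 4800, "r")])
        assert annotate_regions(regions, genes)["r"] == "promoter"

    def test_promoter_clipped_at_zero(self):
        g = GeneAnnotation("g", "chr1", 300, 2000, "+")
        p = promoter_interval(g, 1000)
        assert (p.start, p.end) == (0, 300)

    def test_labels_partition_regions(self, rng):
        regions = random_region_set(rng, 80, span=10_000)
        labels = annotate_regions(regions, self.genes)
        assert len(labels) == len(regions)
        assert set(labels.unique()) <= {"promoter", "genic", "nongenic"}
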