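"""Annotation class construction, SNP assignment, densities, Venn counts."""

import numpy as np
import pytest

from dafscan.classes import (
    ClassCatalog,
    assign_snps_to_classes,
    build_catalog,
    class_density_report,
    coding_regions,
    distance_to_nearest_gene,
    gene_span_regions,
    intersection_counts,
    promoter_regions,
    snps_per_kb,
    splice_control_regions,
    subset_constrained,
)
from dafscan.model import GenomicInterval, PolarizedSNP, RegionSet

from conftest import make_gene


def _spans(rs):
    return sorted((i.chrom, i.start, i.end) for i in rs.merged().intervals)


def _snp(snp_id, chrom, pos):
    return PolarizedSNP(snp_id, chrom, pos, "A", "G", {"AFR": 0.1}, "chimp")


class TestPromoter:
    def test_plus_strand_window(self):
        g = make_gene("g", "chr1", "+", [(10_000, 12_000)])
        assert _spans(promoter_regions([g])) == [("chr1", 9_000, 10_201)]

    def test_minus_strand_window_mirrored(self):
        # TSS base of a - strand transcript ending at 10001 is position 10000
        g = make_gene("g", "chr1", "-", [(8_000, 10_001)])
        assert _spans(promoter_regions([g])) == [("chr1", 9_800, 11_001)]

    def test_clipped_at_chromosome_start(self):
        g = make_gene("g", "chr1", "+", [(500, 1_500)])
        assert _spans(promoter_regions([g])) == [("chr1", 0, 701)]

    def test_unstranded_gene_rejected(self):
        g = make_gene("g", "chr1", "+", [(10_000, 12_000)])
        g.strand = "."
        with pytest.raises(ValueError, match="strand"):
            promoter_regions([g])


class TestSpliceControl:
    def test_plus_strand_acceptor_and_donor(self):
        # exon [800,1000), intron [1000,1200), exon [1200,1300)
        g = make_gene("g", "chr1", "+", [(800, 1000), (1200, 1300)])
        rs = splice_control_regions([g])
        # donor at 1000: 3 exonic + 6 intronic -> [997, 1006)
        # acceptor at 1200: 50 intronic + 2 exonic -> [1150, 1202)
        assert _spans(rs) == [("chr1", 997, 1006), ("chr1", 1150, 1202)]

    def test_minus_strand_hand_enumerated(self):
        # same physical exons on -: transcript reads right-to-left, so the
        # donor sits at the right junction and the acceptor at the left one.
        # donor at 1200: exonic [1200,1203) + intronic [1194,1200) = [1194,1203)
        # acceptor at 1000: intronic [1000,1050) + exonic [998,1000) = [998,1050)
        g = make_gene("g", "chr1", "-", [(800, 1000), (1200, 1300)])
        assert _spans(splice_control_regions([g])) == [
            ("chr1", 998, 1050),
            ("chr1", 1194, 1203),
        ]

    def test_windows_clipped_to_short_exon_and_intron(self):
        # exon [995,1000) (len 5 > 3 exonic ok), intron [1000,1004) (len 4 < 6)
        g = make_gene("g", "chr1", "+", [(995, 1000), (1004, 1010)])
        rs = splice_control_regions([g])
        # donor: [997,1000)+[1000,1004); acceptor: intronic clipped to
        # [1000,1004), exonic [1004,1006) -> all pieces merge into [997,1006)
        assert _spans(rs) == [("chr1", 997, 1006)]

    def test_single_exon_contributes_nothing(self):
        g = make_gene("g", "chr1", "+", [(800, 1000)])
        assert len(splice_control_regions([g])) == 0

    def test_strand_symmetry_under_reverse_complement(self):
        L = 100_000  # flip coordinates: [s,e) -> [L-e, L-s), strand swapped
        exons = [(20_800, 21_000), (21_200, 21_300), (22_000, 22_500)]
        fwd = make_gene("g", "chr1", "+", exons)
        rev = make_gene("g", "chr1", "-", [(L - e, L - s) for s, e in reversed(exons)])
        for builder in (promoter_regions, splice_control_regions):
            got = {(L - e, L - s) for _, s, e in _spans(builder([rev]))}
            expect = {(s, e) for _, s, e in _spans(builder([fwd]))}
            assert got == expect


class TestCodingAndSpans:
    def test_cds_union(self):
        g = make_gene("g", "chr1", "+", [(100, 400)], [(100, 200), (300, 400)])
        rs = coding_regions([g])
        assert _spans(rs) == [("chr1", 100, 200), ("chr1", 300, 400)]
        assert rs.total_length_bp == 200

    def test_overlapping_cds_merged_across_transcripts(self):
        g1 = make_gene("g1", "chr1", "+", [(100, 250)], [(100, 200)])
        g2 = make_gene("g2", "chr2", "+", [(100, 250)], [(150, 250)])
        g2.chrom = "chr1"
        for tx in g2.transcripts:
            for itv_list in (tx.exons, tx.cds):
                itv_list[:] = [GenomicInterval("chr1", i.start, i.end, i.strand) for i in itv_list]
        g2.span = GenomicInterval("chr1", 100, 250, "+")
        assert _spans(coding_regions([g1, g2])) == [("chr1", 100, 250)]

    def test_no_cds_yields_empty_set(self):
        g = make_gene("g", "chr1", "+", [(100, 400)])
        assert len(coding_regions([g])) == 0


class TestDistance:
    def test_gap_and_overlap(self):
        genes = [make_gene("g", "chr1", "+", [(6_000, 9_000)])]
        assert distance_to_nearest_gene(GenomicInterval("chr1", 5_000, 5_001), genes) == 999
        assert distance_to_nearest_gene(_snp("s", "chr1", 7_000), genes) == 0
        assert distance_to_nearest_gene(_snp("s", "chr2", 7_000), genes) == np.inf

    def test_min_gap_over_genes_matches_bruteforce(self):
        genes = [
            make_gene("a", "chr1", "+", [(1_000, 2_000)]),
            make_gene("b", "chr1", "+", [(5_000, 6_000)]),
            make_gene("c", "chr1", "+", [(9_000, 9_500)]),
        ]
        q = GenomicInterval("chr1", 3_100, 3_200)
        brute = min(
            max(g.span.start - q.end, q.start - g.span.end, 0) for g in genes
        )
        assert distance_to_nearest_gene(q, genes) == brute == 1100


class TestSubsetConstrained:
    def test_subtraction_truncates(self):
        ce = RegionSet("ce", [GenomicInterval("chr1", 100, 300)])
        genes = [make_gene("g", "chr1", "+", [(200, 400)])]
        out = subset_constrained(ce, genes, "minus_genes")
        assert _spans(out) == [("chr1", 100, 200)]

    def test_min_distance_keeps_or_drops_whole_elements(self):
        ce = RegionSet("ce", [GenomicInterval("chr1", 100, 300)])
        genes = [make_gene("g", "chr1", "+", [(800, 900)])]
        # distance 500 < 1000 -> dropped atomically
        assert len(subset_constrained(ce, genes, "min_distance", 1_000)) == 0
        assert _spans(subset_constrained(ce, genes, "min_distance", 400)) == [
            ("chr1", 100, 300)
        ]

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            subset_constrained(RegionSet("ce", []), [], "bogus")

    def test_all_rules_match_per_base_enumeration(self):
        genes = [
            make_gene("g1", "chr1", "+", [(1_000, 3_000)], [(1_200, 2_800)]),
            make_gene("g2", "chr1", "-", [(8_000, 9_000)], [(8_100, 8_900)]),
        ]
        ce = RegionSet(
            "ce",
            [
                GenomicInterval("chr1", 500, 1_500),   # overlaps g1
                GenomicInterval("chr1", 2_900, 3_200), # straddles g1 end
                GenomicInterval("chr1", 4_000, 4_100), # between genes
                GenomicInterval("chr1", 7_000, 7_050), # 950 bp from g2
                GenomicInterval("chr1", 9_500, 9_700), # 500 bp from g2
            ],
        )
        gene_bases = set(range(1_000, 3_000)) | set(range(8_000, 9_000))
        cds_bases = set(range(1_200, 2_800)) | set(range(8_100, 8_900))
        ce_bases = set().union(*(range(i.start, i.end) for i in ce.intervals))
        assert {
            b
            for i in subset_constrained(ce, genes, "minus_genes").intervals
            for b in range(i.start, i.end)
        } == ce_bases - gene_bases
        assert {
            b
            for i in subset_constrained(ce, genes, "minus_coding").intervals
            for b in range(i.start, i.end)
        } == ce_bases - cds_bases
        for d, expected_kept in [(400, {4_000, 7_000, 9_500}), (1_000, {4_000})]:
            kept = {i.start for i in subset_constrained(ce, genes, "min_distance", d).intervals}
            assert kept == expected_kept

    def test_min_distance_memberships_nest_monotonically(self, demo_bundle):
        ce = demo_bundle.region_sets["constrained"]
        genes = demo_bundle.genes
        near = {i.start for i in subset_constrained(ce, genes, "min_distance", 1_000).intervals}
        far = {i.start for i in subset_constrained(ce, genes, "min_distance", 100_000).intervals}
        outside = {
            i.start
            for i in ce.intervals
            if distance_to_nearest_gene(i, genes) > 0
        }
        assert far <= near <= outside


class TestAssignment:
    def test_half_open_membership(self):
        catalog = ClassCatalog()
        catalog.add(RegionSet("c", [GenomicInterval("chr1", 100, 200)]))
        snps = [_snp("in", "chr1", 150), _snp("edge", "chr1", 200), _snp("first", "chr1", 100)]
        members = assign_snps_to_classes(snps, catalog)
        assert members.ids("c") == {"in", "first"}

    def test_random_instance_matches_quadratic_oracle(self):
        rng = np.random.default_rng(21)
        catalog = ClassCatalog()
        itvs = [
            GenomicInterval("chr1", int(s), int(s + l))
            for s, l in zip(rng.integers(0, 5_000, 20), rng.integers(1, 400, 20))
        ]
        catalog.add(RegionSet("c", itvs))
        snps = [_snp(f"s{i}", "chr1", int(p)) for i, p in enumerate(rng.integers(0, 5_500, 200))]
        members = assign_snps_to_classes(snps, catalog)
        brute = {
            s.snp_id
            for s in snps
            if any(i.start <= s.pos < i.end for i in itvs)
        }
        assert members.ids("c") == brute


class TestDensityReport:
    @pytest.mark.parametrize(
        "n,size_kb,expected",
        [(132_562, 34_215, 3.87), (11_307_522, 3_022_647, 3.74), (0, 10, 0.0)],
    )
    def test_density_rounding(self, n, size_kb, expected):
        assert snps_per_kb(n, size_kb) == expected

    def test_report_on_catalog(self):
        catalog = ClassCatalog()
        catalog.add(RegionSet("c", [GenomicInterval("chr1", 0, 10_000)]))
        snps = [_snp(f"s{i}", "chr1", i * 100) for i in range(37)]
        report = class_density_report(assign_snps_to_classes(snps, catalog), catalog)
        row = report.set_index("class").loc["c"]
        assert row["n_snps"] == 37 and row["size_kb"] == 10.0
        assert row["snps_per_kb"] == 3.7

    def test_zero_length_class_reports_nan_not_error(self):
        catalog = ClassCatalog()
        catalog.add(RegionSet("empty", []))
        report = class_density_report(assign_snps_to_classes([], catalog), catalog)
        assert np.isnan(report.iloc[0]["snps_per_kb"])


class TestIntersections:
    def _membership(self, assignments):
        catalog = ClassCatalog()
        snps = []
        for label, positions in assignments.items():
            catalog.add(
                RegionSet(label, [GenomicInterval("chr1", p, p + 1) for p in positions])
            )
            snps.extend(_snp(f"p{p}", "chr1", p) for p in positions)
        uniq = {s.snp_id: s for s in snps}
        return assign_snps_to_classes(uniq.values(), catalog)

    def test_disjoint_classes(self):
        members = self._membership({"A": [10, 20, 30], "B": [100, 110, 120, 130]})
        counts = intersection_counts(members, ["A", "B"])
        assert counts == {"A": 3, "B": 4, "A&B": 0}

    def test_subset_class(self):
        members = self._membership({"A": [10, 20], "B": [10, 20, 30]})
        counts = intersection_counts(members, ["A", "B"])
        assert counts["A"] == 0 and counts["A&B"] == 2 and counts["B"] == 1

    def test_three_classes_match_set_algebra(self):
        rng = np.random.default_rng(5)
        sets = {lab: list(rng.choice(500, size=60, replace=False)) for lab in "ABC"}
        members = self._membership(sets)
        counts = intersection_counts(members, ["A", "B", "C"])
        A, B, C = (set(sets[k]) for k in "ABC")
        assert counts["A"] == len(A - B - C)
        assert counts["A&B"] == len((A & B) - C)
        assert counts["A&B&C"] == len(A & B & C)
        assert sum(counts.values()) == len(A | B | C)

    def test_more_than_four_labels_rejected(self):
        members = self._membership({lab: [i] for i, lab in enumerate("ABCDE")})
        with pytest.raises(ValueError, match="2-4"):
            intersection_counts(members, list("ABCDE"))


def test_build_catalog_derives_expected_classes(demo_bundle, demo_polarized):
    polarized, _ = demo_polarized
    catalog = build_catalog(demo_bundle.genes, demo_bundle.region_sets)
    labels = set(catalog.labels())
    assert {
        "promoter", "splice_site", "coding", "constrained", "ancestral_repeats",
        "constrained_minus_coding", "constrained_minus_genes",
        "constrained_1kb_from_genes", "constrained_100kb_from_genes",
    } <= labels
    members = assign_snps_to_classes(polarized, catalog)
    # subtraction conservation at bundle scale
    ce = catalog.region_sets["constrained"]
    minus = catalog.region_sets["constrained_minus_genes"]
    spans = gene_span_regions(demo_bundle.genes)
    inter = sum(
        min(i.end, j.end) - max(i.start, j.start)
        for i in ce.merged().intervals
        for j in spans.intervals
        if i.chrom == j.chrom and i.start < j.end and j.start < i.end
    )
    assert minus.total_length_bp + inter == ce.total_length_bp
    # classes are not mutually exclusive: constrained SNPs also in its subsets
    assert members.ids("constrained_minus_genes") <= members.ids("constrained")
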