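"""Panel regions, VCF extraction, cohort MAF and rare-variant filters."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from modyscreen import (
    PanelVariant,
    compute_cohort_maf,
    extract_panel_variants,
    filter_variants,
    load_gene_regions,
)
from modyscreen.cohortsim import packaged_fixture_path
from modyscreen.variants import normalize_allele

from conftest import write_test_bed, write_test_vcf


def make_variant(n_het=0, n_hom=0, n_called=10, depth=30.0):
    return PanelVariant(
        chrom="7",
        pos=1500,
        ref="A",
        alt="G",
        gene="GCK",
        het_carriers=frozenset(f"h{i}" for i in range(n_het)),
        hom_carriers=frozenset(f"H{i}" for i in range(n_hom)),
        n_called=n_called,
        mean_depth=depth,
    )


class TestGeneRegions:
    def test_packaged_panel_has_16_genes_in_genomic_order(self):
        regions = load_gene_regions(packaged_fixture_path("panel_grch38.bed"))
        assert len(regions) == 16
        assert {r.gene for r in regions} == {
            "HNF4A", "GCK", "HNF1A", "PDX1", "HNF1B", "NEUROD1", "KLF11",
            "CEL", "PAX4", "INS", "BLK", "ABCC8", "KCNJ11", "APPL1",
            "RFX6", "NKX6-1",
        }
        keys = [((0, int(r.chrom)) if r.chrom.isdigit() else (1, r.chrom), r.start) for r in regions]
        assert keys == sorted(keys)
        subtype = {r.gene: r.mody_subtype for r in regions}
        assert subtype["HNF4A"] == 1 and subtype["APPL1"] == 14
        assert subtype["RFX6"] == "candidate"

    @pytest.mark.parametrize(
        "rows, match",
        [
            ([("7", 2000, 1000, "GCK")], "start"),
            ([("7", 1000, 2000, "TP53")], "not in the 16-gene panel"),
            ([("7", 1000, 2000, "GCK"), ("7", 3000, 4000, "GCK")], "duplicate"),
            ([("7", 1000, 2000)], "columns"),
        ],
    )
    def test_malformed_bed_rejected_with_line_number(self, tmp_path, rows, match):
        bed = write_test_bed(tmp_path / "bad.bed", rows)
        with pytest.raises(ValueError, match=match):
            load_gene_regions(bed)

    def test_empty_bed_rejected(self, tmp_path):
        bed = tmp_path / "empty.bed"
        bed.write_text("# only comments\n")
        with pytest.raises(ValueError, match="no regions"):
            load_gene_regions(bed)


class TestNormalization:
    @pytest.mark.parametrize(
        "pos, ref, alt, expected",
        [
            (100, "A", "G", (100, "A", "G")),
            (100, "TA", "CA", (100, "T", "C")),  # shared suffix
            (100, "AT", "AC", (101, "T", "C")),  # shared prefix shifts pos
            (100, "GCGC", "GTGC", (101, "C", "T")),
            (100, "AT", "A", (100, "AT", "A")),  # deletion untouched
            (100, "CTT", "CT", (100, "CT", "C")),  # parsimony-trimmed indel
        ],
    )
    def test_parsimony_trimming(self, pos, ref, alt, expected):
        assert normalize_allele(pos, ref, alt) == expected


class TestExtraction:
    BED = [("7", 1000, 2000, "GCK")]

    def test_coordinate_conversion_boundaries(self, tmp_path):
        """1-based position region_start+1 is the first base inside a 0-based
        half-open region; position == start (0-based) is outside."""
        bed = write_test_bed(tmp_path / "p.bed", self.BED)
        vcf = write_test_vcf(
            tmp_path / "v.vcf",
            ["s1"],
            [
                dict(chrom="7", pos=1000, ref="A", alt="G", gts=["0/1"]),  # outside
                dict(chrom="7", pos=1001, ref="A", alt="G", gts=["0/1"]),  # first inside
                dict(chrom="7", pos=2000, ref="A", alt="G", gts=["0/1"]),  # last inside
                dict(chrom="7", pos=2001, ref="A", alt="G", gts=["0/1"]),  # outside
            ],
        )
        variants = extract_panel_variants(vcf, load_gene_regions(bed))
        assert [v.pos for v in variants] == [1001, 2000]
        assert all(v.gene == "GCK" for v in variants)

    def test_multiallelic_split_and_carriers(self, tmp_path):
        bed = write_test_bed(tmp_path / "p.bed", self.BED)
        vcf = write_test_vcf(
            tmp_path / "v.vcf",
            ["s1", "s2", "s3", "s4"],
            [
                dict(
                    chrom="7", pos=1500, ref="A", alt=["T", "C"],
                    gts=["0/1", "0/2", "1/2", "2/2"],
                )
            ],
        )
        variants = extract_panel_variants(vcf, load_gene_regions(bed))
        assert len(variants) == 2
        by_alt = {v.alt: v for v in variants}
        assert by_alt["T"].het_carriers == frozenset({"s1", "s3"})
        assert by_alt["T"].hom_carriers == frozenset()
        assert by_alt["C"].het_carriers == frozenset({"s2", "s3"})
        assert by_alt["C"].hom_carriers == frozenset({"s4"})
        assert all(v.n_called == 4 for v in variants)

    def test_missing_genotypes_excluded_from_denominator(self, tmp_path):
        bed = write_test_bed(tmp_path / "p.bed", self.BED)
        vcf = write_test_vcf(
            tmp_path / "v.vcf",
            ["s1", "s2", "s3"],
            [dict(chrom="7", pos=1500, ref="A", alt="G", gts=["0/1", "./.", "0/0"])],
        )
        (v,) = extract_panel_variants(vcf, load_gene_regions(bed))
        assert v.n_called == 2
        assert compute_cohort_maf(v) == pytest.approx(0.25)

    def test_record_order_independence(self, tmp_path):
        bed = write_test_bed(tmp_path / "p.bed", self.BED)
        recs = [
            dict(chrom="7", pos=p, ref="A", alt="G", gts=["0/1", "0/0"])
            for p in (1500, 1200, 1900)
        ]
        v1 = extract_panel_variants(
            write_test_vcf(tmp_path / "a.vcf", ["s1", "s2"], recs),
            load_gene_regions(bed),
        )
        v2 = extract_panel_variants(
            write_test_vcf(tmp_path / "b.vcf", ["s1", "s2"], recs[::-1]),
            load_gene_regions(bed),
        )
        assert [(v.pos, v.het_carriers) for v in v1] == [
            (v.pos, v.het_carriers) for v in v2
        ]

    def test_contig_mismatch_names_contigs(self, tmp_path):
        bed = write_test_bed(tmp_path / "p.bed", self.BED)
        vcf = write_test_vcf(
            tmp_path / "v.vcf",
            ["s1"],
            [dict(chrom="X", pos=1500, ref="A", alt="G", gts=["0/1"])],
        )
        with pytest.raises(ValueError, match="contig"):
            extract_panel_variants(vcf, load_gene_regions(bed))

    def test_info_dp_fallback_when_format_dp_absent(self, tmp_path):
        bed = write_test_bed(tmp_path / "p.bed", self.BED)
        vcf = write_test_vcf(
            tmp_path / "v.vcf",
            ["s1", "s2"],
            [dict(chrom="7", pos=1500, ref="A", alt="G", gts=["0/1", "0/0"],
                  dp=None, info_dp=84)],
        )
        (v,) = extract_panel_variants(vcf, load_gene_regions(bed))
        assert v.mean_depth == pytest.approx(42.0)


class TestCohortMAF:
    def test_hand_counted_example(self):
        # 1 het + 1 hom in 10 called subjects: 3 alt alleles / 20
        assert compute_cohort_maf(make_variant(n_het=1, n_hom=1)) == pytest.approx(0.15)

    def test_eleven_hets_in_full_cohort(self):
        v = make_variant(n_het=11, n_called=14364)
        assert round(compute_cohort_maf(v), 6) == 0.000383

    def test_no_carriers_zero(self):
        assert compute_cohort_maf(make_variant()) == 0.0

    def test_no_called_genotypes_rejected(self):
        with pytest.raises(ValueError):
            compute_cohort_maf(make_variant(n_called=0))

    def test_major_alt_is_folded(self):
        v = make_variant(n_hom=9, n_called=10)
        assert compute_cohort_maf(v) == pytest.approx(0.1)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    gt_matrix=st.lists(
        st.lists(st.integers(-1, 1), min_size=2, max_size=2),
        min_size=1,
        max_size=25,
    )
)
def test_maf_matches_brute_force_allele_tally(tmp_path_factory, gt_matrix):
    """Extraction + MAF equals a numpy allele tally over the genotype matrix."""
    tmp = tmp_path_factory.mktemp("maf")
    samples = [f"s{i}" for i in range(len(gt_matrix))]
    gts = ["/".join("." if a < 0 else str(a) for a in row) for row in gt_matrix]
    bed = write_test_bed(tmp / "p.bed", [("7", 1000, 2000, "GCK")])
    vcf = write_test_vcf(
        tmp / "v.vcf", samples, [dict(chrom="7", pos=1500, ref="A", alt="G", gts=gts)]
    )
    (v,) = extract_panel_variants(vcf, load_gene_regions(bed))

    arr = np.array(gt_matrix)
    called = (arr >= 0).all(axis=1)
    alt_alleles = int(arr[called].sum())
    assert v.n_called == int(called.sum())
    assert len(v.het_carriers) + 2 * len(v.hom_carriers) == alt_alleles
    if called.any():
        f = alt_alleles / (2 * called.sum())
        assert compute_cohort_maf(v) == pytest.approx(min(f, 1 - f))
    else:
        with pytest.raises(ValueError):
            compute_cohort_maf(v)


class TestFilters:
    def test_maf_boundary_strict(self):
        # 2 het among 1000 called = MAF exactly 0.001 -> dropped
        at = make_variant(n_het=2, n_called=1000)
        below = make_variant(n_het=1, n_called=1000)
        assert filter_variants([at, below]) == [below]

    def test_depth_boundary_strict(self):
        at = make_variant(n_het=1, n_called=10000, depth=20.0)
        above = make_variant(n_het=1, n_called=10000, depth=20.01)
        assert filter_variants([at, above]) == [above]

    def test_carrierless_variants_dropped(self):
        assert filter_variants([make_variant(n_het=0)]) == []

    def test_raising_maf_max_is_monotone(self):
        variants = [
            make_variant(n_het=h, n_called=1000, depth=30.0) for h in (1, 3, 5, 9)
        ]
        kept_tight = filter_variants(variants, maf_max=0.002)
        kept_loose = filter_variants(variants, maf_max=0.004)
        assert set(id(v) for v in kept_tight) <= set(id(v) for v in kept_loose)

    def test_order_preserved(self):
        variants = [make_variant(n_het=1, n_called=10**k) for k in (5, 3, 4)]
        assert filter_variants(variants) == variants


def test_het_hom_overlap_rejected():
    with pytest.raises(ValueError, match="disjoint"):
        PanelVariant(
            chrom="7", pos=1, ref="A", alt="G", gene="GCK",
            het_carriers=frozenset({"s1"}), hom_carriers=frozenset({"s1"}),
            n_called=2, mean_depth=30.0,
        )
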