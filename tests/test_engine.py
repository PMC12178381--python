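"""Analysis engine: target genes, coverage, classification, rates."""

from fractions import Fraction

import pytest

import panelaudit as pa
from panelaudit.annotation import GeneModel, TranscriptModel
from panelaudit.bed import PanelDefinition
from panelaudit.engine import (
    ANY_OVERLAP,
    AnalysisError,
    classify_variants,
    exon_coverage_table,
    gene_coverage,
    identify_target_genes,
    noncovered_mutation_rate,
)
from panelaudit.intervals import GenomicInterval, IntervalSet
from panelaudit.variants import VariantRecord


def gene(symbol="A", exons=((101, 300),), chrom="chr1"):
    return GeneModel(
        symbol=symbol,
        chrom=chrom,
        transcripts=[
            TranscriptModel(
                transcript_id=f"NM_{symbol}",
                exons=[GenomicInterval(chrom, s, e) for s, e in exons],
            )
        ],
    )


def panel(target, mask=(), name="P"):
    return PanelDefinition(
        name=name,
        target=IntervalSet.from_tuples(target),
        mask=IntervalSet.from_tuples(mask),
    )


def ann(*genes):
    return pa.GenomeAnnotation(list(genes))


def snv(chrom="chr1", pos=150, gene_symbol="A", source="COSMIC", pos_samples=5, tested=1000):
    kwargs = {}
    if source == "COSMIC":
        kwargs = {"positive_samples": pos_samples, "tested_samples": tested}
    return VariantRecord(
        source=source,
        record_id=f"V{pos}",
        gene_symbol=gene_symbol,
        chrom=chrom,
        start=pos,
        end=pos,
        classification="Tier 1" if source == "COSMIC" else "Pathogenic",
        **kwargs,
    )


class TestTargetGenes:
    def test_single_base_overlap_suffices(self):
        a = ann(gene())
        assert identify_target_genes(panel([("chr1", 300, 400)]), a) == {"A"}

    def test_intronic_only_coverage_is_not_targeting(self):
        a = ann(gene(exons=((101, 200), (401, 500))))
        assert identify_target_genes(panel([("chr1", 250, 350)]), a) == set()

    def test_mask_is_ignored_for_membership(self):
        a = ann(gene())
        p = panel([("chr1", 101, 300)], mask=[("chr1", 101, 300)])
        assert identify_target_genes(p, a) == {"A"}

    def test_fixture_panel_hits_exactly_planted_genes(
        self, beta_panel, annotation, manifest
    ):
        assert identify_target_genes(beta_panel, annotation) == set(
            manifest["panels"]["BETA"]["target_genes"]
        )


class TestGeneCoverage:
    def test_arithmetic(self):
        g = gene(exons=((101, 300),))  # 200 exon bases
        p = panel([("chr1", 121, 200)], mask=[("chr1", 181, 200)])  # 80 targeted, 20 masked
        stat = gene_coverage(g, p)
        assert stat.targeted_bases == 80
        assert stat.targeted_masked_bases == 20
        assert stat.coverage_fraction == Fraction(80, 200) == Fraction(2, 5)
        assert stat.effective_coverage_fraction == Fraction(60, 200)

    def test_full_coverage_empty_mask(self):
        stat = gene_coverage(gene(), panel([("chr1", 1, 1000)]))
        assert stat.coverage_fraction == 1
        assert stat.effective_coverage_fraction == 1

    def test_conservation_identity(self, annotation, alpha_panel):
        # targeted + untargeted = exon union, for every fixture gene
        for sym in annotation.symbols():
            g = annotation.genes[sym]
            stat = gene_coverage(g, alpha_panel)
            untargeted = g.exon_union.subtract(alpha_panel.target).total_length
            assert stat.targeted_bases + untargeted == stat.exon_union_bases

    def test_cds_only_denominator(self):
        g = GeneModel(
            symbol="C",
            chrom="chr1",
            transcripts=[
                TranscriptModel(
                    transcript_id="NM_C",
                    exons=[GenomicInterval("chr1", 101, 300)],
                    cds_span=GenomicInterval("chr1", 151, 250),
                )
            ],
        )
        stat = gene_coverage(g, panel([("chr1", 101, 200)]), cds_only=True)
        assert stat.exon_union_bases == 100  # CDS union
        assert stat.targeted_bases == 50


class TestExonTable:
    def test_boundary_arithmetic(self):
        a = ann(gene(exons=((101, 200),)))
        rows = exon_coverage_table(a, panel([("chr1", 150, 400)]))
        (row,) = rows
        assert row.covered_bases == 51
        assert row.exon_bases == 100

    def test_untargeted_exon_row_present(self):
        a = ann(gene(exons=((101, 200), (301, 400))))
        rows = exon_coverage_table(a, panel([("chr1", 101, 200)]))
        assert len(rows) == 2
        assert rows[1].covered_bases == 0

    def test_fixture_exons_match_manifest(self, alpha_analysis, manifest):
        expected = manifest["panels"]["ALPHA"]["exon_coverage"]
        for r in alpha_analysis.exon_table:
            assert expected[f"{r.transcript_id}|{r.exon_number}"] == [
                r.covered_bases,
                r.masked_covered_bases,
            ]


class TestClassification:
    def test_targeted_unmasked_snv_is_detectable(self):
        p = panel([("chr1", 100, 200)])
        (cv,) = classify_variants([snv(pos=150)], p)
        assert cv.targeted and not cv.masked and cv.detectable

    def test_partial_deletion_not_targeted_under_containment(self):
        p = panel([("chr1", 100, 154)])
        deletion = VariantRecord(
            source="COSMIC", record_id="D", gene_symbol="A", chrom="chr1",
            start=150, end=159, classification="Tier 1",
            positive_samples=1, tested_samples=100,
        )
        (contained,) = classify_variants([deletion], p)
        assert not contained.targeted
        (any_rule,) = classify_variants([deletion], p, overlap_rule=ANY_OVERLAP)
        assert any_rule.targeted

    def test_single_masked_base_suppresses(self):
        p = panel([("chr1", 100, 200)], mask=[("chr1", 150, 150)])
        (cv,) = classify_variants([snv(pos=150)], p)
        assert cv.targeted and cv.masked and not cv.detectable

    def test_fixture_labels_match_manifest_under_both_rules(
        self, alpha_panel, variant_tables, manifest
    ):
        clinvar, cosmic = variant_tables
        labels = manifest["variant_labels"]["ALPHA"]
        for rule, key in (("contained", "targeted_contained"), ("any", "targeted_any")):
            for cv in classify_variants(clinvar + cosmic, alpha_panel, overlap_rule=rule):
                lab = labels[f"{cv.record.source}:{cv.record.record_id}"]
                assert cv.targeted == lab[key]
                assert cv.masked == lab["masked"]

    def test_boundary_straddlers_planted(self, manifest):
        # the fixture must exercise the rule difference
        diff = [
            k
            for k, lab in manifest["variant_labels"]["ALPHA"].items()
            if lab["targeted_any"] != lab["targeted_contained"]
        ]
        assert diff


class TestNoncoveredRate:
    def test_summation(self):
        p = panel([("chr1", 1000, 1001)])  # neither variant targeted
        cvs = classify_variants(
            [snv(pos=150, pos_samples=3, tested=1000), snv(pos=151, pos_samples=2, tested=1000)],
            p,
        )
        assert noncovered_mutation_rate(cvs, {"A"}, "target_genes", True) == pytest.approx(
            0.005
        )

    def test_all_detectable_gives_zero(self):
        p = panel([("chr1", 100, 200)])
        cvs = classify_variants([snv(pos=150)], p)
        assert noncovered_mutation_rate(cvs, {"A"}, "all_genes", True) == 0.0

    def test_clinvar_record_is_hard_error(self):
        p = panel([("chr1", 100, 200)])
        cvs = classify_variants([snv(pos=150, source="CLINVAR")], p)
        with pytest.raises(AnalysisError, match="sample frequency"):
            noncovered_mutation_rate(cvs, {"A"})

    def test_scope_and_mask_monotonicity(self, alpha_analysis):
        s = alpha_analysis.summary
        assert s.target_genes_masked >= s.target_genes_unmasked
        assert s.all_genes_masked >= s.all_genes_unmasked
        assert s.all_genes_masked >= s.target_genes_masked
        assert s.all_genes_unmasked >= s.target_genes_unmasked

    def test_fixture_rates_match_manifest(
        self, alpha_panel, annotation, variant_tables, manifest
    ):
        _, cosmic = variant_tables
        for rule in ("contained", "any"):
            a = pa.analyze_panel(
                alpha_panel, annotation, cosmic_variants=cosmic, overlap_rule=rule
            )
            assert a.summary.as_dict() == manifest["rates"]["ALPHA"][rule]


class TestAnalyzePanel:
    def test_counters_equal_groupby_of_classified(self, alpha_analysis):
        from collections import defaultdict

        tallies = defaultdict(lambda: [0, 0, 0, 0, 0, 0])
        for cv in alpha_analysis.classified_variants:
            idx = 0 if cv.record.source == "CLINVAR" else 3
            t = tallies[cv.record.gene_symbol]
            t[idx] += 1
            if cv.targeted:
                t[idx + 1] += 1
                if cv.masked:
                    t[idx + 2] += 1
        for g in alpha_analysis.gene_stats:
            t = tallies.get(g.gene_symbol, [0] * 6)
            assert [
                g.clinvar_total, g.clinvar_targeted, g.clinvar_targeted_masked,
                g.cosmic_total, g.cosmic_targeted, g.cosmic_targeted_masked,
            ] == t

    def test_fully_masked_gene_is_target_without_detectable_variants(
        self, alpha_analysis
    ):
        stat = alpha_analysis.gene_stat("GENE05")
        assert stat.fully_masked
        assert "GENE05" in alpha_analysis.target_gene_set
        assert stat.effective_coverage_fraction == 0
        detectable = [
            cv
            for cv in alpha_analysis.classified_variants
            if cv.record.gene_symbol == "GENE05" and cv.detectable
        ]
        assert detectable == []

    def test_empty_mask_zeroes_all_masked_counters(self, beta_analysis):
        assert all(g.targeted_masked_bases == 0 for g in beta_analysis.gene_stats)
        assert all(not cv.masked for cv in beta_analysis.classified_variants)

    def test_symbol_unmatched_variant_flagged(self, alpha_analysis):
        unmatched = [
            cv for cv in alpha_analysis.classified_variants if cv.symbol_unmatched
        ]
        assert unmatched
        assert all(cv.record.gene_symbol == "GENEX" for cv in unmatched)

    def test_chromosome_mismatch_errors_without_force(self, annotation):
        p = panel([("chr9", 1, 100)])
        with pytest.raises(AnalysisError, match="no chromosome shared"):
            pa.analyze_panel(p, annotation)
        forced = pa.analyze_panel(p, annotation, force=True)
        assert forced.target_gene_set == set()

    def test_coordinate_join_attributes_by_overlap(
        self, alpha_panel, annotation, variant_tables
    ):
        """Under the coordinate join a variant counts for every gene whose
        exon union overlaps its span, regardless of its symbol field."""
        clinvar, cosmic = variant_tables
        a = pa.analyze_panel(
            alpha_panel, annotation, clinvar, cosmic, variant_gene_join="coordinate"
        )
        from collections import defaultdict

        expected = defaultdict(int)
        for cv in a.classified_variants:
            span = GenomicInterval(cv.record.chrom, cv.record.start, cv.record.end)
            for sym, g in annotation.genes.items():
                if g.exon_union.overlaps(span):
                    expected[sym] += 1
        for g in a.gene_stats:
            assert g.clinvar_total + g.cosmic_total == expected[g.gene_symbol]
        # the annotation-unknown symbol's variants are now attributed to the
        # gene they actually fall in
        genex_total = sum(
            1 for cv in a.classified_variants if cv.record.gene_symbol == "GENEX"
        )
        assert genex_total > 0

    def test_effective_never_exceeds_raw_coverage(self, alpha_analysis):
        for g in alpha_analysis.gene_stats:
            assert g.effective_coverage_fraction <= g.coverage_fraction
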