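"""Workspace comparisons, gene search, and advertised-list audits."""

import math

import pytest

import panelaudit as pa
from panelaudit.compare import (
    FOLD_FINITE,
    PanelWorkspace,
    WorkspaceError,
    audit_advertised,
    compare_exons,
    compare_gene_metrics,
    search_genes,
)


class TestCompareGeneMetrics:
    def test_row_count_is_union_of_target_sets(self, workspace, alpha_analysis, beta_analysis):
        table = compare_gene_metrics(workspace, "exon_base", ("ALPHA", "BETA"))
        union = alpha_analysis.target_gene_set | beta_analysis.target_gene_set
        assert len(table) == len(union)
        assert set(table["gene"]) == union

    def test_fold_change_ratio(self, workspace):
        table = compare_gene_metrics(workspace, "exon_base", ("ALPHA", "BETA"))
        row = table[table["gene"] == "GENE30"].iloc[0]
        m1, m2 = row["masked_value_ALPHA"], row["masked_value_BETA"]
        assert row["fold_change"] == pytest.approx(max(m1, m2) / min(m1, m2))
        assert row["fold_category"] == FOLD_FINITE

    def test_gene_in_one_panel_gets_sentinel(self, workspace):
        table = compare_gene_metrics(workspace, "exon_base", ("ALPHA", "BETA"))
        only_alpha = table[table["gene"] == "GENE01"].iloc[0]
        assert only_alpha["value_BETA"] == 0.0
        assert math.isinf(only_alpha["fold_change"])
        assert only_alpha["fold_category"] == "only_in_ALPHA"

    def test_min_fold_keeps_sentinels_filters_finite(self, workspace):
        full = compare_gene_metrics(workspace, "exon_base", ("ALPHA", "BETA"))
        filtered = compare_gene_metrics(
            workspace, "exon_base", ("ALPHA", "BETA"), min_fold=2.0
        )
        finite = filtered[filtered["fold_category"] == FOLD_FINITE]
        assert (finite["fold_change"] >= 2.0).all()
        sentinels = full[full["fold_category"] != FOLD_FINITE]
        assert len(filtered[filtered["fold_category"] != FOLD_FINITE]) == len(sentinels)

    def test_table_reproducible_from_archives(self, workspace, alpha_analysis, beta_analysis, tmp_path):
        # brute-force recomputation from round-tripped archives
        for a in (alpha_analysis, beta_analysis):
            pa.write_archive(a, str(tmp_path / f"{a.panel_name}.pau.zip"))
        ws2 = PanelWorkspace.from_dir(str(tmp_path))
        t1 = compare_gene_metrics(workspace, "cosmic", ("ALPHA", "BETA"))
        t2 = compare_gene_metrics(ws2, "cosmic", ("ALPHA", "BETA"))
        assert t1.equals(t2)

    def test_unknown_panel_name(self, workspace):
        with pytest.raises(WorkspaceError, match="GAMMA"):
            compare_gene_metrics(workspace, "exon_base", ("ALPHA", "GAMMA"))


class TestSearchGenes:
    def test_all_targeted_verdicts(self, workspace):
        # six genes targeted by both panels
        shared = ["GENE02", "GENE03", "GENE05", "GENE06", "GENE07", "GENE30"]
        res = search_genes(workspace, shared)
        assert res.all_targeted == {"ALPHA": True, "BETA": True}
        # GENE01 is an ALPHA-only target
        res2 = search_genes(workspace, shared + ["GENE01"])
        assert res2.all_targeted == {"ALPHA": True, "BETA": False}

    def test_case_insensitive_and_unknown_symbols(self, workspace):
        res = search_genes(workspace, ["gene02", "NOSUCHGENE"])
        assert res.unknown_symbols == ["NOSUCHGENE"]
        assert list(res.grid.index) == ["GENE02"]

    def test_insertion_order_invariance(self, alpha_analysis, beta_analysis):
        q = ["GENE02", "GENE05"]
        a = search_genes(PanelWorkspace([alpha_analysis, beta_analysis]), q)
        b = search_genes(PanelWorkspace([beta_analysis, alpha_analysis]), q)
        assert a.all_targeted == b.all_targeted

    def test_empty_query_rejected(self, workspace):
        with pytest.raises(ValueError):
            search_genes(workspace, [])


class TestCompareExons:
    def test_rows_align_by_exon_identity(self, workspace, manifest):
        df = compare_exons(workspace, "GENE05", ["ALPHA", "BETA"])
        expected = manifest["panels"]["ALPHA"]["exon_coverage"]
        for _, row in df.iterrows():
            key = f"{row['transcript_id']}|{row['exon_number']}"
            covered, masked = expected[key]
            assert row["covered_frac_ALPHA"] == covered / row["exon_bases"]
            assert row["masked_frac_ALPHA"] == masked / row["exon_bases"]

    def test_untargeted_gene_gives_all_zero_table(self, workspace):
        df = compare_exons(workspace, "GENE25")  # targeted by neither panel
        value_cols = [c for c in df.columns if c.startswith(("covered_", "masked_"))]
        assert (df[value_cols] == 0).all().all()

    def test_unknown_gene_raises(self, workspace):
        with pytest.raises(WorkspaceError, match="NOSUCH"):
            compare_exons(workspace, "NOSUCH")


class TestAuditAdvertised:
    def test_set_algebra(self, alpha_analysis):
        # advertised {A..E} vs detected {A,B,C,F} shape, on fixture symbols
        targets = sorted(alpha_analysis.target_gene_set)
        advertised = targets[:3] + ["GENE09", "GENE11"]  # 9/11 untargeted
        rep = audit_advertised(alpha_analysis, advertised)
        assert rep.advertised_not_detected == ["GENE09", "GENE11"]
        assert rep.detected_not_advertised == targets[3:]

    def test_perfect_agreement_is_all_empty(self, beta_analysis):
        rep = audit_advertised(beta_analysis, sorted(beta_analysis.target_gene_set))
        assert rep.advertised_not_detected == []
        assert rep.detected_not_advertised == []
        assert rep.fully_masked_targets == []
        assert rep.unknown_advertised == []

    def test_unknown_symbols_reported_separately(self, alpha_analysis):
        rep = audit_advertised(alpha_analysis, ["GENE02", "MADEUPGENE"])
        assert rep.unknown_advertised == ["MADEUPGENE"]

    def test_fixture_audit_matches_manifest(self, alpha_analysis, bundle, manifest):
        with open(bundle.advertised_paths["ALPHA"]) as fh:
            advertised = [l.strip() for l in fh if l.strip()]
        rep = audit_advertised(alpha_analysis, advertised)
        expected = manifest["advertised"]["ALPHA"]["expected"]
        assert rep.advertised_not_detected == expected["advertised_not_detected"]
        assert rep.detected_not_advertised == expected["detected_not_advertised"]
        assert rep.fully_masked_targets == expected["fully_masked_targets"]
        assert rep.unknown_advertised == expected["unknown_advertised"]

    def test_lists_are_disjoint(self, alpha_analysis, bundle):
        with open(bundle.advertised_paths["ALPHA"]) as fh:
            advertised = [l.strip() for l in fh if l.strip()]
        rep = audit_advertised(alpha_analysis, advertised)
        lists = [
            set(rep.advertised_not_detected),
            set(rep.detected_not_advertised),
            set(rep.fully_masked_targets),
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not (lists[i] & lists[j])


def test_provenance_mismatch_warns(alpha_analysis, beta_analysis):
    from dataclasses import replace

    other = pa.PanelAnalysis(
        panel_name="OTHER",
        panel_sources=beta_analysis.panel_sources,
        gene_stats=beta_analysis.gene_stats,
        exon_table=beta_analysis.exon_table,
        classified_variants=beta_analysis.classified_variants,
        target_gene_set=beta_analysis.target_gene_set,
        summary=beta_analysis.summary,
        db_versions={"annotation": "a-different-snapshot"},
    )
    ws = PanelWorkspace([alpha_analysis, other])
    assert ws.provenance_warnings()
    same = PanelWorkspace([alpha_analysis])
    assert same.provenance_warnings() == []
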