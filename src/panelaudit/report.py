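"""TSV/JSON exports and static figures for panel analyses.

Everything the interactive views of a panel-audit workflow would show is
exported here as flat files: per-gene statistics, the exon table, the
classified ClinVar/COSMIC variant tables (with outbound database
hyperlinks), the four-setting noncovered-mutation-rate summary, and a
two-panel comparison figure (per-gene scatter plus horizontal columns with
the masked portion drawn as a shaded segment).
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Optional

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .compare import record_url, transcript_url
from .engine import PanelAnalysis
from .variants import COSMIC


def render_rate(rate: float) -> str:
    """Human rendering of a noncovered mutation rate.

    A rate r > 0 is the expected number of missed oncogenic mutations per
    sample, so one sample in round(1/r) harbors one: 0.005 -> "1 in 200".
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0:
        return "0 (none missed)"
    return f"1 in {round(1 / rate)}"


def gene_stats_frame(analysis: PanelAnalysis) -> pd.DataFrame:
    rows = []
    for g in analysis.gene_stats:
        rows.append(
            {
                "gene": g.gene_symbol,
                "is_target": int(g.is_target),
                "exon_union_bases": g.exon_union_bases,
                "targeted_bases": g.targeted_bases,
                "targeted_masked_bases": g.targeted_masked_bases,
                "coverage_pct": round(float(g.coverage_fraction) * 100, 4),
                "effective_coverage_pct": round(
                    float(g.effective_coverage_fraction) * 100, 4
                ),
                "clinvar_total": g.clinvar_total,
                "clinvar_targeted": g.clinvar_targeted,
                "clinvar_targeted_masked": g.clinvar_targeted_masked,
                "cosmic_total": g.cosmic_total,
                "cosmic_targeted": g.cosmic_targeted,
                "cosmic_targeted_masked": g.cosmic_targeted_masked,
            }
        )
    return pd.DataFrame(rows)


def exon_table_frame(analysis: PanelAnalysis) -> pd.DataFrame:
    rows = []
    for r in analysis.exon_table:
        rows.append(
            {
                "gene": r.gene_symbol,
                "transcript_id": r.transcript_id,
                "exon_number": r.exon_number,
                "chrom": r.exon_interval.chrom,
                "start": r.exon_interval.start,
                "end": r.exon_interval.end,
                "exon_bases": r.exon_bases,
                "covered_bases": r.covered_bases,
                "masked_covered_bases": r.masked_covered_bases,
                "coverage_pct": round(float(r.coverage_fraction) * 100, 4),
                "transcript_url": transcript_url(r.transcript_id),
            }
        )
    return pd.DataFrame(rows)


def variant_frame(analysis: PanelAnalysis, source: str) -> pd.DataFrame:
    rows = []
    for cv in analysis.classified_variants:
        r = cv.record
        if r.source != source:
            continue
        row = {
            "record_id": r.record_id,
            "gene": r.gene_symbol,
            "chrom": r.chrom,
            "start": r.start,
            "end": r.end,
            "classification": r.classification,
            "targeted": int(cv.targeted),
            "masked": int(cv.masked),
            "detectable": int(cv.detectable),
            "symbol_unmatched": int(cv.symbol_unmatched),
            "url": record_url(r.source, r.record_id),
        }
        if r.source == COSMIC:
            row["positive_samples"] = r.positive_samples
            row["tested_samples"] = r.tested_samples
            row["sample_frequency"] = r.sample_frequency
        rows.append(row)
    return pd.DataFrame(rows)


def summary_dict(analysis: PanelAnalysis) -> Dict[str, object]:
    rates = analysis.summary.as_dict()
    return {
        "panel_name": analysis.panel_name,
        "panel_sources": list(analysis.panel_sources),
        "db_versions": analysis.db_versions,
        "overlap_rule": analysis.overlap_rule,
        "cds_only": analysis.cds_only,
        "n_target_genes": len(analysis.target_gene_set),
        "target_genes": sorted(analysis.target_gene_set),
        "noncovered_mutation_rates": rates,
        "noncovered_mutation_rates_rendered": {
            k: render_rate(v) for k, v in rates.items()
        },
    }


def export_analysis(analysis: PanelAnalysis, outdir: str) -> List[str]:
    """Write the five standard exports; returns the paths written."""
    os.makedirs(outdir, exist_ok=True)
    paths = []
    for fname, df in (
        ("gene_stats.tsv", gene_stats_frame(analysis)),
        ("exon_table.tsv", exon_table_frame(analysis)),
        ("clinvar_classified.tsv", variant_frame(analysis, "CLINVAR")),
        ("cosmic_classified.tsv", variant_frame(analysis, COSMIC)),
    ):
        path = os.path.join(outdir, fname)
        df.to_csv(path, sep="\t", index=False)
        paths.append(path)
    path = os.path.join(outdir, "summary.json")
    with open(path, "w") as fh:
        json.dump(summary_dict(analysis), fh, indent=1, sort_keys=True)
    paths.append(path)
    return paths


def comparison_figure(
    table: pd.DataFrame,
    panels: tuple,
    metric: str,
    path: Optional[str] = None,
    max_bars: int = 40,
):
    """Two-panel comparison figure: per-gene scatter and horizontal columns.

    In the column panel the mask-adjusted value is the solid bar and the
    masked-away portion is a lighter shaded extension, so extensively
    masked genes stand out.
    """
    name1, name2 = panels
    fig, (ax1, ax2) = plt.subplots(
        1, 2, figsize=(11, max(4, min(12, 0.28 * min(len(table), max_bars) + 2)))
    )
    ax1.scatter(
        table[f"value_{name1}"], table[f"value_{name2}"], s=12, alpha=0.7,
        color="#1f6fb4",
    )
    lim = max(1e-9, table[[f"value_{name1}", f"value_{name2}"]].to_numpy().max())
    ax1.plot([0, lim], [0, lim], lw=0.8, ls="--", color="grey")
    ax1.set_xlabel(f"{metric} coverage, {name1}")
    ax1.set_ylabel(f"{metric} coverage, {name2}")
    ax1.set_title("per-gene coverage")

    sub = table.copy()
    sub["diff"] = (sub[f"masked_value_{name1}"] - sub[f"masked_value_{name2}"]).abs()
    sub = sub.sort_values("diff", ascending=False).head(max_bars)
    sub = sub.iloc[::-1]
    y = range(len(sub))
    for offset, name, color in ((0.2, name1, "#1f6fb4"), (-0.2, name2, "#d1722f")):
        solid = sub[f"masked_value_{name}"]
        full = sub[f"value_{name}"]
        ax2.barh(
            [i + offset for i in y], full, height=0.35, color=color, alpha=0.30,
        )
        ax2.barh(
            [i + offset for i in y], solid, height=0.35, color=color,
            label=f"{name} (unmasked portion solid)",
        )
    ax2.set_yticks(list(y))
    ax2.set_yticklabels(sub["gene"], fontsize=6)
    ax2.set_xlabel(f"{metric} coverage (shaded = masked portion)")
    ax2.set_title("largest between-panel differences")
    ax2.legend(fontsize=7, loc="lower right")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
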