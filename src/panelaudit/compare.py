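"""Cross-panel comparison, gene search and advertised-list auditing.

A :class:`PanelWorkspace` is a collection of completed panel analyses,
typically loaded from a directory of archives.  Analyses built against
different annotation or database snapshots may coexist (comparing across
versions is sometimes exactly the point), but every report then carries a
provenance warning.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd

from .annotation import GenomeAnnotation
from .archive import ARCHIVE_SUFFIX, read_archive
from .engine import PanelAnalysis
from .variants import CLINVAR, COSMIC

log = logging.getLogger(__name__)

METRICS = ("exon_base", "clinvar", "cosmic")

FOLD_FINITE = "finite"
FOLD_BOTH_ZERO = "both_zero"


class WorkspaceError(ValueError):
    pass


class PanelWorkspace:
    """Analyses keyed by panel name, with a shared-provenance check."""

    def __init__(self, analyses: Iterable[PanelAnalysis] = ()) -> None:
        self.analyses: Dict[str, PanelAnalysis] = {}
        for a in analyses:
            self.add(a)

    def add(self, analysis: PanelAnalysis) -> None:
        if analysis.panel_name in self.analyses:
            raise WorkspaceError(f"duplicate panel name {analysis.panel_name!r}")
        self.analyses[analysis.panel_name] = analysis

    @classmethod
    def from_dir(cls, directory: str) -> "PanelWorkspace":
        """Load every ``*.pau.zip`` archive found directly in *directory*."""
        ws = cls()
        for fname in sorted(os.listdir(directory)):
            if fname.endswith(ARCHIVE_SUFFIX):
                ws.add(read_archive(os.path.join(directory, fname)))
        return ws

    def __len__(self) -> int:
        return len(self.analyses)

    def __getitem__(self, name: str) -> PanelAnalysis:
        try:
            return self.analyses[name]
        except KeyError:
            raise WorkspaceError(
                f"unknown panel {name!r}; workspace has {sorted(self.analyses)}"
            ) from None

    @property
    def names(self) -> List[str]:
        return sorted(self.analyses)

    def provenance_warnings(self) -> List[str]:
        versions = {
            name: tuple(sorted(a.db_versions.items()))
            for name, a in self.analyses.items()
        }
        if len(set(versions.values())) <= 1:
            return []
        msg = (
            "panels were analyzed against differing annotation/database "
            f"versions: { {k: dict(v) for k, v in versions.items()} }"
        )
        log.warning(msg)
        return [msg]


def _metric_values(
    analysis: PanelAnalysis, symbol: str, metric: str
) -> Tuple[float, float]:
    """(raw value, mask-adjusted value) of a coverage metric for one gene.

    exon_base: fraction of exon-union bases targeted.  clinvar / cosmic:
    fraction of the gene's registered database alterations that are
    targeted.  The mask-adjusted value excludes masked bases/variants.
    Genes absent from an analysis (or with an empty variant denominator)
    score zero.
    """
    g = analysis.gene_stat(symbol)
    if g is None:
        return 0.0, 0.0
    if metric == "exon_base":
        return float(g.coverage_fraction), float(g.effective_coverage_fraction)
    if metric == "clinvar":
        total, tgt, msk = g.clinvar_total, g.clinvar_targeted, g.clinvar_targeted_masked
    elif metric == "cosmic":
        total, tgt, msk = g.cosmic_total, g.cosmic_targeted, g.cosmic_targeted_masked
    else:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if total == 0:
        return 0.0, 0.0
    return tgt / total, (tgt - msk) / total


def compare_gene_metrics(
    ws: PanelWorkspace,
    metric: str,
    panels: Tuple[str, str],
    min_fold: Optional[float] = None,
) -> pd.DataFrame:
    """Per-gene metric table for a pair of panels.

    One row per gene in the union of the two target gene sets.  The fold
    change is computed on mask-adjusted values; when one side is zero it is
    reported as a sentinel category (``only_in_<panel>``) rather than a
    number, and ``min_fold`` filtering applies only to finite ratios
    (sentinel rows are always retained).
    """
    name1, name2 = panels
    a1, a2 = ws[name1], ws[name2]
    genes = sorted(a1.target_gene_set | a2.target_gene_set)
    rows = []
    for gene in genes:
        v1, m1 = _metric_values(a1, gene, metric)
        v2, m2 = _metric_values(a2, gene, metric)
        if m1 > 0 and m2 > 0:
            fold = m1 / m2 if m1 >= m2 else m2 / m1
            category = FOLD_FINITE
        elif m1 > 0:
            fold = math.inf
            category = f"only_in_{name1}"
        elif m2 > 0:
            fold = math.inf
            category = f"only_in_{name2}"
        else:
            fold = math.nan
            category = FOLD_BOTH_ZERO
        rows.append(
            {
                "gene": gene,
                f"value_{name1}": v1,
                f"value_{name2}": v2,
                f"masked_value_{name1}": m1,
                f"masked_value_{name2}": m2,
                "fold_change": fold,
                "fold_category": category,
            }
        )
    df = pd.DataFrame(rows)
    if min_fold is not None and not df.empty:
        keep = (df["fold_category"] != FOLD_FINITE) | (df["fold_change"] >= min_fold)
        df = df[keep].reset_index(drop=True)
    return df


@dataclass
class GeneSearchResult:
    """Coverage grid for queried genes across panels."""

    grid: pd.DataFrame  # rows: genes; columns: panels; values: coverage fraction
    all_targeted: Dict[str, bool]
    unknown_symbols: List[str]


def search_genes(
    ws: PanelWorkspace,
    genes: Sequence[str],
    panels: Optional[Sequence[str]] = None,
    annotation: Optional[GenomeAnnotation] = None,
) -> GeneSearchResult:
    """Coverage of the queried genes in each panel, plus an all-targeted verdict.

    Symbols are matched case-insensitively against the panels' gene tables
    (or the annotation when supplied); unmatched symbols are reported in
    ``unknown_symbols``, never silently dropped.
    """
    if not genes:
        raise ValueError("at least one gene symbol required")
    panel_names = list(panels) if panels else ws.names
    known: Dict[str, str] = {}
    for name in panel_names:
        for g in ws[name].gene_stats:
            known.setdefault(g.gene_symbol.upper(), g.gene_symbol)
    resolved: List[str] = []
    unknown: List[str] = []
    for q in genes:
        canonical = None
        if annotation is not None:
            canonical = annotation.resolve_symbol(q)
        if canonical is None:
            canonical = known.get(q.upper())
        (resolved if canonical else unknown).append(canonical or q)
    resolved_unique = list(dict.fromkeys(resolved))

    grid = pd.DataFrame(index=resolved_unique, columns=panel_names, dtype=float)
    verdict: Dict[str, bool] = {}
    for name in panel_names:
        a = ws[name]
        for gene in resolved_unique:
            v, _ = _metric_values(a, gene, "exon_base")
            grid.loc[gene, name] = v
        verdict[name] = bool(resolved_unique) and all(
            g in a.target_gene_set for g in resolved_unique
        )
    return GeneSearchResult(grid=grid, all_targeted=verdict, unknown_symbols=unknown)


def compare_exons(
    ws: PanelWorkspace,
    gene: str,
    panels: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Exon-level coverage for one gene, pivoted by panel.

    One row per (transcript, exon); per panel, covered and masked-covered
    fractions.  A gene untargeted by every queried panel yields an all-zero
    table; a gene absent from the exon tables raises.
    """
    panel_names = list(panels) if panels else ws.names
    rows: Dict[Tuple[str, int], Dict[str, object]] = {}
    found = False
    for name in panel_names:
        for r in ws[name].exon_table:
            if r.gene_symbol.upper() != gene.upper():
                continue
            found = True
            key = (r.transcript_id, r.exon_number)
            row = rows.setdefault(
                key,
                {
                    "gene": r.gene_symbol,
                    "transcript_id": r.transcript_id,
                    "exon_number": r.exon_number,
                    "chrom": r.exon_interval.chrom,
                    "start": r.exon_interval.start,
                    "end": r.exon_interval.end,
                    "exon_bases": r.exon_bases,
                },
            )
            row[f"covered_frac_{name}"] = r.covered_bases / r.exon_bases
            row[f"masked_frac_{name}"] = r.masked_covered_bases / r.exon_bases
    if not found:
        raise WorkspaceError(f"gene {gene!r} not present in any panel's annotation")
    df = pd.DataFrame(
        [rows[k] for k in sorted(rows)],
    )
    return df.reset_index(drop=True)


@dataclass
class DiscrepancyReport:
    """Advertised vs. confirmed target-gene audit for one panel.

    The three gene lists are disjoint: genes advertised but never targeted;
    target genes absent from the advertised list; and targeted genes whose
    entire targeted region is masked (zero effective coverage, so no
    reportable calls despite being a target gene).  Advertised symbols not
    found in the annotation at all are listed separately.
    """

    panel_name: str
    advertised_not_detected: List[str] = field(default_factory=list)
    detected_not_advertised: List[str] = field(default_factory=list)
    fully_masked_targets: List[str] = field(default_factory=list)
    unknown_advertised: List[str] = field(default_factory=list)

    def as_dict(self) -> Dict[str, object]:
        return {
            "panel_name": self.panel_name,
            "advertised_not_detected": self.advertised_not_detected,
            "detected_not_advertised": self.detected_not_advertised,
            "fully_masked_targets": self.fully_masked_targets,
            "unknown_advertised": self.unknown_advertised,
        }


def audit_advertised(
    analysis: PanelAnalysis,
    advertised: Sequence[str],
    annotation: Optional[GenomeAnnotation] = None,
) -> DiscrepancyReport:
    """Audit a panel's advertised gene list against its confirmed target genes."""
    if not advertised:
        raise ValueError("advertised gene list is empty")
    known = {g.gene_symbol.upper(): g.gene_symbol for g in analysis.gene_stats}

    resolved: List[str] = []
    unknown: List[str] = []
    for sym in dict.fromkeys(advertised):
        canonical = None
        if annotation is not None:
            canonical = annotation.resolve_symbol(sym)
        if canonical is None:
            canonical = known.get(sym.upper())
        (resolved if canonical else unknown).append(canonical or sym)

    adv = set(resolved)
    targets = analysis.target_gene_set
    detected_not_adv = sorted(targets - adv)
    # keep the three lists disjoint: a fully masked non-advertised target is
    # reported once, under detected_not_advertised
    fully_masked = sorted(
        g.gene_symbol
        for g in analysis.gene_stats
        if g.fully_masked and g.gene_symbol in (targets & adv)
    )
    return DiscrepancyReport(
        panel_name=analysis.panel_name,
        advertised_not_detected=sorted(adv - targets),
        detected_not_advertised=detected_not_adv,
        fully_masked_targets=fully_masked,
        unknown_advertised=sorted(unknown),
    )


def record_url(source: str, record_id: str) -> str:
    """Outbound hyperlink for a database record, for report exports."""
    if source == CLINVAR:
        return f"https://www.ncbi.nlm.nih.gov/clinvar/variation/{record_id}/"
    if source == COSMIC:
        return f"https://cancer.sanger.ac.uk/cosmic/search?q={record_id}"
    return ""


def transcript_url(transcript_id: str) -> str:
    return f"https://www.ncbi.nlm.nih.gov/nuccore/{transcript_id}"
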