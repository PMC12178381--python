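"""Per-panel analysis: target genes, mask-aware coverage, variant classification.

The procedure, given one panel and the shared reference data:

1. *Target genes* — genes whose exon union overlaps the panel target
   regions by at least one base.  The mask is deliberately ignored here: a
   gene whose entire targeted region is masked is still a target gene, it
   just yields no reportable calls (reported as targeted-but-undetectable).
2. *Gene coverage* — per gene, the targeted and targeted-and-masked base
   counts against the exon-union denominator (or the CDS union under
   ``cds_only``).  Fractions are exact integer ratios.
3. *Variant classification* — each database mutation is *targeted* when
   its full reference span is contained in the target set (default; the
   ``any`` rule instead requires a single overlapping base), *masked* when
   any base of its span overlaps the mask, and *detectable* when targeted
   and not masked.  A partially captured indel cannot be reliably called,
   while one masked base suffices to suppress a call.
4. *Noncovered mutation rate* — the sum of positive-sample proportions of
   tier 1-3 mutations the panel misses, i.e. the expected number of missed
   oncogenic mutations per sequenced sample, computed for target genes
   only vs. all genes, with and without the mask.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

from .annotation import GeneModel, GenomeAnnotation
from .bed import PanelDefinition
from .intervals import GenomicInterval, IntervalSet
from .variants import COSMIC, VariantRecord

log = logging.getLogger(__name__)

CONTAINED = "contained"
ANY_OVERLAP = "any"


class AnalysisError(RuntimeError):
    pass


@dataclass(frozen=True)
class GeneCoverageStat:
    """Coverage of one gene's exon union by a panel, plus variant tallies."""

    gene_symbol: str
    exon_union_bases: int
    targeted_bases: int
    targeted_masked_bases: int
    clinvar_total: int = 0
    clinvar_targeted: int = 0
    clinvar_targeted_masked: int = 0
    cosmic_total: int = 0
    cosmic_targeted: int = 0
    cosmic_targeted_masked: int = 0

    def __post_init__(self) -> None:
        if not (
            0 <= self.targeted_masked_bases <= self.targeted_bases <= self.exon_union_bases
        ):
            raise AnalysisError(
                f"{self.gene_symbol}: inconsistent base counts "
                f"(masked {self.targeted_masked_bases} <= targeted "
                f"{self.targeted_bases} <= union {self.exon_union_bases} violated)"
            )

    @property
    def coverage_fraction(self) -> Fraction:
        """targeted / exon-union bases, exact."""
        return Fraction(self.targeted_bases, self.exon_union_bases)

    @property
    def effective_coverage_fraction(self) -> Fraction:
        """Targeted *and unmasked* fraction — where variants are reportable."""
        return Fraction(
            self.targeted_bases - self.targeted_masked_bases, self.exon_union_bases
        )

    @property
    def is_target(self) -> bool:
        return self.targeted_bases >= 1

    @property
    def fully_masked(self) -> bool:
        return self.targeted_bases > 0 and self.targeted_masked_bases == self.targeted_bases


@dataclass(frozen=True)
class ExonCoverageRow:
    gene_symbol: str
    transcript_id: str
    exon_number: int
    exon_interval: GenomicInterval
    covered_bases: int
    masked_covered_bases: int

    @property
    def exon_bases(self) -> int:
        return self.exon_interval.length

    @property
    def coverage_fraction(self) -> Fraction:
        return Fraction(self.covered_bases, self.exon_bases)


@dataclass(frozen=True)
class ClassifiedVariant:
    """A VariantRecord with its panel-relative status."""

    record: VariantRecord
    targeted: bool
    masked: bool
    symbol_unmatched: bool = False

    @property
    def detectable(self) -> bool:
        return self.targeted and not self.masked


@dataclass(frozen=True)
class NoncoveredRateSummary:
    """Expected missed tier 1-3 mutations per sample, under four settings."""

    target_genes_masked: float
    target_genes_unmasked: float
    all_genes_masked: float
    all_genes_unmasked: float

    def as_dict(self) -> Dict[str, float]:
        return {
            "target_genes_masked": self.target_genes_masked,
            "target_genes_unmasked": self.target_genes_unmasked,
            "all_genes_masked": self.all_genes_masked,
            "all_genes_unmasked": self.all_genes_unmasked,
        }


@dataclass
class PanelAnalysis:
    """The complete, serializable result bundle for one panel."""

    panel_name: str
    panel_sources: Tuple[str, ...]
    gene_stats: List[GeneCoverageStat]
    exon_table: List[ExonCoverageRow]
    classified_variants: List[ClassifiedVariant]
    target_gene_set: Set[str]
    summary: NoncoveredRateSummary
    db_versions: Dict[str, str] = field(default_factory=dict)
    overlap_rule: str = CONTAINED
    cds_only: bool = False

    def gene_stat(self, symbol: str) -> Optional[GeneCoverageStat]:
        return self._index.get(symbol)

    @property
    def _index(self) -> Dict[str, GeneCoverageStat]:
        idx = getattr(self, "_index_cache", None)
        if idx is None:
            idx = {g.gene_symbol: g for g in self.gene_stats}
            object.__setattr__(self, "_index_cache", idx)
        return idx

    @property
    def has_cosmic(self) -> bool:
        return any(v.record.source == COSMIC for v in self.classified_variants)


# ---------------------------------------------------------------------------
# operations


def identify_target_genes(
    panel: PanelDefinition, ann: GenomeAnnotation
) -> Set[str]:
    """Genes with >= 1 exon-union base inside the panel target regions.

    The mask is not consulted: a fully masked targeted gene is still a
    target gene.
    """
    hits = {
        g.symbol
        for g in ann.genes.values()
        if g.exon_union.intersect(panel.target).total_length >= 1
    }
    if not hits:
        log.warning("panel %s: no target genes identified", panel.name)
    return hits


def gene_coverage(
    gene: GeneModel, panel: PanelDefinition, cds_only: bool = False
) -> GeneCoverageStat:
    """Base-level coverage of one gene (variant tallies left at zero)."""
    union = gene.cds_union if cds_only else gene.exon_union
    targeted = union.intersect(panel.target)
    masked = targeted.intersect(panel.mask)
    return GeneCoverageStat(
        gene_symbol=gene.symbol,
        exon_union_bases=union.total_length,
        targeted_bases=targeted.total_length,
        targeted_masked_bases=masked.total_length,
    )


def exon_coverage_table(
    ann: GenomeAnnotation, panel: PanelDefinition
) -> List[ExonCoverageRow]:
    """One row per (transcript, exon) for every annotated gene.

    Rows are emitted even for untargeted exons (covered_bases = 0) so that
    exon-level comparisons align across panels.
    """
    masked_target = panel.masked_target
    rows: List[ExonCoverageRow] = []
    for symbol in ann.symbols():
        gene = ann.genes[symbol]
        for tx in gene.transcripts:
            for ordinal, exon in enumerate(tx.exons, 1):
                exon_set = IntervalSet([exon])
                covered = exon_set.intersect(panel.target).total_length
                masked_cov = exon_set.intersect(masked_target).total_length
                rows.append(
                    ExonCoverageRow(
                        gene_symbol=symbol,
                        transcript_id=tx.transcript_id,
                        exon_number=ordinal,
                        exon_interval=exon,
                        covered_bases=covered,
                        masked_covered_bases=masked_cov,
                    )
                )
    return rows


def classify_variants(
    variants: Iterable[VariantRecord],
    panel: PanelDefinition,
    overlap_rule: str = CONTAINED,
    known_symbols: Optional[Set[str]] = None,
) -> List[ClassifiedVariant]:
    """Label each variant targeted / masked / detectable relative to a panel."""
    if overlap_rule not in (CONTAINED, ANY_OVERLAP):
        raise ValueError(f"unknown overlap rule {overlap_rule!r}")
    out: List[ClassifiedVariant] = []
    for rec in variants:
        span = GenomicInterval(rec.chrom, rec.start, rec.end)
        if overlap_rule == CONTAINED:
            targeted = panel.target.contains(span)
        else:
            targeted = panel.target.overlaps(span)
        masked = panel.mask.overlaps(span)
        unmatched = known_symbols is not None and rec.gene_symbol not in known_symbols
        out.append(
            ClassifiedVariant(
                record=rec, targeted=targeted, masked=masked, symbol_unmatched=unmatched
            )
        )
    return out


def noncovered_mutation_rate(
    classified: Sequence[ClassifiedVariant],
    target_gene_set: Set[str],
    scope: str = "target_genes",
    use_mask: bool = True,
) -> float:
    """Sum of positive-sample proportions over mutations the panel misses.

    A mutation is missed when it is not targeted, or (with masking) when it
    is masked.  Only COSMIC records carry sample frequencies; passing a
    ClinVar record is a hard error.
    """
    if scope not in ("target_genes", "all_genes"):
        raise ValueError(f"unknown scope {scope!r}")
    freqs: List[float] = []
    for cv in classified:
        freq = cv.record.sample_frequency
        if freq is None:
            raise AnalysisError(
                f"variant {cv.record.record_id} ({cv.record.source}) has no "
                "sample frequency; noncovered rates are defined for COSMIC "
                "records only"
            )
        if scope == "target_genes" and cv.record.gene_symbol not in target_gene_set:
            continue
        missed = (not cv.targeted) or (use_mask and cv.masked)
        if missed:
            freqs.append(freq)
    return math.fsum(freqs)


def _variant_tallies(
    classified: Sequence[ClassifiedVariant],
    source: str,
    ann: Optional[GenomeAnnotation] = None,
) -> Dict[str, Tuple[int, int, int]]:
    """Per-gene (total, targeted, targeted-and-masked) variant counts.

    Default attribution is the database's own gene symbol; when *ann* is
    given, variants are instead attributed by coordinate overlap with each
    gene's exon union (a span inside two overlapping genes counts for
    both).
    """
    out: Dict[str, List[int]] = {}
    for cv in classified:
        if cv.record.source != source:
            continue
        if ann is None:
            symbols = [cv.record.gene_symbol]
        else:
            span = GenomicInterval(cv.record.chrom, cv.record.start, cv.record.end)
            symbols = [
                g.symbol for g in ann.genes.values() if g.exon_union.overlaps(span)
            ]
        for symbol in symbols:
            t = out.setdefault(symbol, [0, 0, 0])
            t[0] += 1
            if cv.targeted:
                t[1] += 1
                if cv.masked:
                    t[2] += 1
    return {k: (v[0], v[1], v[2]) for k, v in out.items()}


def analyze_panel(
    panel: PanelDefinition,
    ann: GenomeAnnotation,
    clinvar_variants: Sequence[VariantRecord] = (),
    cosmic_variants: Sequence[VariantRecord] = (),
    overlap_rule: str = CONTAINED,
    cds_only: bool = False,
    variant_gene_join: str = "symbol",
    db_versions: Optional[Dict[str, str]] = None,
    force: bool = False,
) -> PanelAnalysis:
    """Run the full per-panel analysis and assemble a :class:`PanelAnalysis`.

    Deterministic for fixed inputs: gene statistics are ordered by symbol
    and variants retain input order.
    """
    ann_chroms = {g.chrom for g in ann.genes.values()}
    if not (set(panel.target.chroms) & ann_chroms):
        msg = (
            f"panel {panel.name}: no chromosome shared between target regions "
            f"({sorted(panel.target.chroms)}) and annotation ({sorted(ann_chroms)})"
        )
        if not force:
            raise AnalysisError(msg + "; pass force=True to proceed")
        log.warning(msg)

    target_genes = identify_target_genes(panel, ann)
    known_symbols = set(ann.genes)

    classified = classify_variants(
        list(clinvar_variants) + list(cosmic_variants),
        panel,
        overlap_rule=overlap_rule,
        known_symbols=known_symbols,
    )
    if variant_gene_join not in ("symbol", "coordinate"):
        raise ValueError(f"unknown variant_gene_join {variant_gene_join!r}")
    join_ann = ann if variant_gene_join == "coordinate" else None
    clinvar_tally = _variant_tallies(classified, "CLINVAR", join_ann)
    cosmic_tally = _variant_tallies(classified, COSMIC, join_ann)

    stats: List[GeneCoverageStat] = []
    skipped_noncoding = 0
    for symbol in ann.symbols():
        gene = ann.genes[symbol]
        if cds_only and not gene.is_coding:
            skipped_noncoding += 1
            continue
        base = gene_coverage(gene, panel, cds_only=cds_only)
        cv = clinvar_tally.get(symbol, (0, 0, 0))
        co = cosmic_tally.get(symbol, (0, 0, 0))
        stats.append(
            replace(
                base,
                clinvar_total=cv[0],
                clinvar_targeted=cv[1],
                clinvar_targeted_masked=cv[2],
                cosmic_total=co[0],
                cosmic_targeted=co[1],
                cosmic_targeted_masked=co[2],
            )
        )
    if skipped_noncoding:
        log.info(
            "cds_only: excluded %d non-coding gene(s) from coverage stats",
            skipped_noncoding,
        )

    cosmic_classified = [c for c in classified if c.record.source == COSMIC]
    summary = NoncoveredRateSummary(
        target_genes_masked=noncovered_mutation_rate(
            cosmic_classified, target_genes, "target_genes", True
        ),
        target_genes_unmasked=noncovered_mutation_rate(
            cosmic_classified, target_genes, "target_genes", False
        ),
        all_genes_masked=noncovered_mutation_rate(
            cosmic_classified, target_genes, "all_genes", True
        ),
        all_genes_unmasked=noncovered_mutation_rate(
            cosmic_classified, target_genes, "all_genes", False
        ),
    )

    return PanelAnalysis(
        panel_name=panel.name,
        panel_sources=panel.source_files,
        gene_stats=stats,
        exon_table=exon_coverage_table(ann, panel),
        classified_variants=classified,
        target_gene_set=target_genes,
        summary=summary,
        db_versions=dict(db_versions or {"annotation": ann.provenance}),
        overlap_rule=overlap_rule,
        cds_only=cds_only,
    )
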