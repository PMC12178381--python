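"""Gene annotation model: genes -> transcripts -> exons, with cached unions.

The coverage denominator used throughout the package is the *exon union* of
a gene: the set-union of the exon intervals of all its annotated
transcripts.  The coding-only alternative (``cds_union``) intersects each
transcript's exons with its CDS span; non-coding transcripts (NR_-style)
contribute nothing to it.

Readers accept GTF, GFF3 and the UCSC refSeq/refGene table dialect.  GTF
and GFF3 coordinates are already 1-based closed; UCSC ``exonStarts`` /
``cdsStart`` are 0-based and converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import gffutils

from .intervals import GenomicInterval, IntervalSet, normalize_chrom

log = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Malformed or internally inconsistent annotation input."""


@dataclass
class TranscriptModel:
    """One transcript: ordered exons (ordinals from 1) and an optional CDS span."""

    transcript_id: str
    exons: List[GenomicInterval]
    cds_span: Optional[GenomicInterval] = None

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start <= a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"{a} and {b}"
                )

    @property
    def exon_intervals(self) -> IntervalSet:
        return IntervalSet(self.exons)

    @property
    def coding_intervals(self) -> IntervalSet:
        if self.cds_span is None:
            return IntervalSet()
        return self.exon_intervals.intersect(IntervalSet([self.cds_span]))


@dataclass
class GeneModel:
    """A gene with its transcripts and precomputed exon/CDS unions."""

    symbol: str
    chrom: str
    transcripts: List[TranscriptModel]
    exon_union: IntervalSet = field(default_factory=IntervalSet)
    cds_union: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self) -> None:
        if not self.exon_union:
            self.exon_union = IntervalSet(
                ex for t in self.transcripts for ex in t.exons
            )
        if not self.cds_union:
            cds = IntervalSet()
            for t in self.transcripts:
                cds = cds.union(t.coding_intervals)
            self.cds_union = cds

    @property
    def is_coding(self) -> bool:
        return bool(self.cds_union)


class GenomeAnnotation:
    """Collection of :class:`GeneModel` keyed by symbol."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        build_label: str = "",
        source_version: str = "",
    ) -> None:
        self.genes: Dict[str, GeneModel] = {}
        for g in genes:
            if g.symbol in self.genes:
                raise AnnotationError(f"duplicate gene symbol {g.symbol!r}")
            self.genes[g.symbol] = g
        self.build_label = build_label
        self.source_version = source_version
        self._upper = {s.upper(): s for s in self.genes}

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.genes

    def get(self, symbol: str) -> Optional[GeneModel]:
        return self.genes.get(symbol)

    def resolve_symbol(self, symbol: str) -> Optional[str]:
        """Case-insensitive lookup returning the canonical annotation symbol."""
        return self._upper.get(symbol.upper())

    def symbols(self) -> List[str]:
        return sorted(self.genes)

    @property
    def provenance(self) -> str:
        return f"{self.source_version or 'unversioned'}|{self.build_label or 'unknown-build'}"


# ---------------------------------------------------------------------------
# readers


def read_annotation(
    path: str,
    dialect: str,
    chrom_style: str = "chr",
    build_label: str = "",
    source_version: str = "",
) -> GenomeAnnotation:
    """Read a gene annotation in ``gtf``, ``gff3`` or ``ucsc_refseq_table`` dialect.

    Genes whose exons fall on several chromosomes are split into one entry
    per chromosome, with the chromosome appended to the symbol, and a
    warning is logged (real refSeq tables contain such records for
    pseudoautosomal genes).
    """
    if dialect in ("gtf", "gff3"):
        raw = _read_gxf(path, dialect, chrom_style)
    elif dialect == "ucsc_refseq_table":
        raw = _read_ucsc_table(path, chrom_style)
    else:
        raise AnnotationError(f"unknown annotation dialect {dialect!r}")
    genes = _assemble_genes(raw)
    return GenomeAnnotation(
        genes,
        build_label=build_label,
        source_version=source_version or f"{dialect}:{path}",
    )


# transcript accumulator: (gene_symbol) -> transcript_id -> (chrom, exons, cds parts)
_RawTx = Dict[Tuple[str, str], Dict[str, object]]


def _read_gxf(path: str, dialect: str, chrom_style: str) -> _RawTx:
    db = gffutils.create_db(
        path,
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    if dialect == "gff3":
        # transcript features carry the gene linkage via Parent=gene ID
        gene_name_by_id: Dict[str, str] = {}
        for g in db.features_of_type(("gene",)):
            gid = g.attributes.get("ID", [g.id])[0]
            gene_name_by_id[gid] = g.attributes.get("Name", [gid])[0]
        tx_gene: Dict[str, str] = {}
        for t in db.features_of_type(("mRNA", "transcript", "ncRNA")):
            tid = t.attributes.get("ID", [t.id])[0]
            parent = t.attributes.get("Parent", [None])[0]
            tx_gene[tid] = gene_name_by_id.get(parent, parent or tid)

    raw: _RawTx = {}
    for kind in ("exon", "CDS"):
        for feat in db.features_of_type(kind):
            chrom = normalize_chrom(feat.seqid, chrom_style)
            if dialect == "gtf":
                tid = _attr(feat, "transcript_id")
                gene = _attr(feat, "gene_name") or _attr(feat, "gene_id")
            else:
                tid = feat.attributes.get("Parent", [None])[0]
                gene = tx_gene.get(tid) if tid else None
            if not tid:
                raise AnnotationError(
                    f"{kind} feature at {feat.seqid}:{feat.start}-{feat.end} "
                    "has no transcript id"
                )
            if not gene:
                raise AnnotationError(
                    f"{kind} feature of transcript {tid} has no gene symbol"
                )
            entry = raw.setdefault((gene, chrom), {}).setdefault(
                tid, {"exons": [], "cds": []}
            )
            iv = GenomicInterval(chrom, feat.start, feat.end)
            entry["exons" if kind == "exon" else "cds"].append(iv)
    return raw


def _attr(feat, name: str) -> Optional[str]:
    vals = feat.attributes.get(name)
    return vals[0] if vals else None


# refGene.txt column order (no header in the wild; an optional leading bin column)
_UCSC_COLS = (
    "name chrom strand txStart txEnd cdsStart cdsEnd "
    "exonCount exonStarts exonEnds score name2"
).split()


def _read_ucsc_table(path: str, chrom_style: str) -> _RawTx:
    raw: _RawTx = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields and fields[0].isdigit():  # leading UCSC bin column
                fields = fields[1:]
            if len(fields) < len(_UCSC_COLS):
                raise AnnotationError(
                    f"{path}:{lineno}: expected >= {len(_UCSC_COLS)} columns, "
                    f"got {len(fields)}"
                )
            row = dict(zip(_UCSC_COLS, fields))
            chrom = normalize_chrom(row["chrom"], chrom_style)
            try:
                starts = [int(x) for x in row["exonStarts"].split(",") if x]
                ends = [int(x) for x in row["exonEnds"].split(",") if x]
                cds_start, cds_end = int(row["cdsStart"]), int(row["cdsEnd"])
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if len(starts) != len(ends):
                raise AnnotationError(
                    f"{path}:{lineno}: exonStarts/exonEnds length mismatch"
                )
            exons = [GenomicInterval(chrom, s + 1, e) for s, e in zip(starts, ends)]
            cds = (
                [GenomicInterval(chrom, cds_start + 1, cds_end)]
                if cds_end > cds_start
                else []
            )
            entry = raw.setdefault((row["name2"], chrom), {})
            if row["name"] in entry:
                raise AnnotationError(
                    f"{path}:{lineno}: duplicate transcript id {row['name']!r}"
                )
            entry[row["name"]] = {"exons": exons, "cds": cds}
    return raw


def _assemble_genes(raw: _RawTx) -> List[GeneModel]:
    by_symbol: Dict[str, List[Tuple[str, Dict[str, object]]]] = {}
    for (symbol, chrom), txs in raw.items():
        by_symbol.setdefault(symbol, []).append((chrom, txs))
    genes: List[GeneModel] = []
    seen_tx: Dict[str, Tuple[str, Tuple]] = {}
    for symbol in sorted(by_symbol):
        entries = by_symbol[symbol]
        multi = len(entries) > 1
        if multi:
            log.warning(
                "gene %s has exons on %d chromosomes; splitting into "
                "per-chromosome entries",
                symbol,
                len(entries),
            )
        for chrom, txs in sorted(entries):
            transcripts = []
            for tid in sorted(txs):
                parts = txs[tid]
                exons: List[GenomicInterval] = parts["exons"]  # type: ignore[assignment]
                if not exons:
                    raise AnnotationError(f"transcript {tid} has no exons")
                key = tuple(sorted((e.chrom, e.start, e.end) for e in exons))
                if tid in seen_tx and seen_tx[tid][1] != key:
                    raise AnnotationError(
                        f"duplicate transcript id {tid!r} with conflicting coordinates"
                    )
                seen_tx[tid] = (symbol, key)
                cds_parts: List[GenomicInterval] = parts["cds"]  # type: ignore[assignment]
                cds_span = None
                if cds_parts:
                    cds_span = GenomicInterval(
                        chrom,
                        min(c.start for c in cds_parts),
                        max(c.end for c in cds_parts),
                    )
                transcripts.append(
                    TranscriptModel(transcript_id=tid, exons=exons, cds_span=cds_span)
                )
            name = f"{symbol}_{chrom}" if multi else symbol
            genes.append(GeneModel(symbol=name, chrom=chrom, transcripts=transcripts))
    return genes
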