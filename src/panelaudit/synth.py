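"""Deterministic synthetic test-data generator with a ground-truth manifest.

Real panel BED files and dated database snapshots are proprietary or too
large to ship, so this module fabricates a complete miniature study: a toy
genome annotation (two chromosomes, ~30 genes with multi-transcript exon
structures, a non-coding gene, an interleaved gene pair), panels with
masks, and ClinVar-/CMC-dialect mutation tables — together with a manifest
recording the ground truth for every quantity the analysis computes.

The manifest is the *oracle*: every value in it is derived by brute-force
per-base set arithmetic over plain Python sets of positions, without using
the package's interval algebra or analysis engine.  Any disagreement
between the engine and the manifest is therefore a genuine defect in one
of two independent computations.

All outputs are pure functions of ``(seed, parameters)``.  The emitted
files reproduce the dialect quirks of their real counterparts (trailing
commas in UCSC exonStarts, unsorted and duplicated BED lines, comment and
track lines, bare chromosome numbers in variant tables, decoy rows that
the readers must drop).
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

OVERLAP_RULES = ("contained", "any")
RATE_SETTINGS = (
    "target_genes_masked",
    "target_genes_unmasked",
    "all_genes_masked",
    "all_genes_unmasked",
)


class GenerationError(RuntimeError):
    pass


Base = Tuple[str, int]  # (chrom, 1-based position)


@dataclass
class TranscriptFixture:
    tid: str
    exons: List[Tuple[int, int]]  # sorted, 1-based closed
    cds: Optional[Tuple[int, int]] = None  # genomic CDS span


@dataclass
class GeneFixture:
    symbol: str
    chrom: str
    transcripts: List[TranscriptFixture]

    @property
    def union_positions(self) -> Set[int]:
        out: Set[int] = set()
        for t in self.transcripts:
            for s, e in t.exons:
                out.update(range(s, e + 1))
        return out

    @property
    def cds_positions(self) -> Set[int]:
        out: Set[int] = set()
        for t in self.transcripts:
            if t.cds is None:
                continue
            cs, ce = t.cds
            for s, e in t.exons:
                lo, hi = max(s, cs), min(e, ce)
                if lo <= hi:
                    out.update(range(lo, hi + 1))
        return out


@dataclass
class GenomeFixture:
    genes: List[GeneFixture]
    chrom_sizes: Dict[str, int]
    gtf_path: str = ""
    gff3_path: str = ""
    ucsc_path: str = ""

    def gene(self, symbol: str) -> GeneFixture:
        for g in self.genes:
            if g.symbol == symbol:
                return g
        raise KeyError(symbol)

    @property
    def all_exon_bases(self) -> Set[Base]:
        out: Set[Base] = set()
        for g in self.genes:
            out.update((g.chrom, p) for p in g.union_positions)
        return out

    def manifest_fragment(self) -> Dict[str, object]:
        return {
            "genes": {
                g.symbol: {
                    "chrom": g.chrom,
                    "exon_union_bases": len(g.union_positions),
                    "cds_union_bases": len(g.cds_positions),
                    "n_transcripts": len(g.transcripts),
                    "coding": bool(g.cds_positions),
                }
                for g in self.genes
            }
        }


@dataclass
class PanelFixture:
    name: str
    target_bases: Set[Base]
    mask_bases: Set[Base]
    target_bed: str
    mask_bed: str = ""
    record_count: int = 0
    comment_lines: int = 0

    def target_genes(self, genome: GenomeFixture) -> List[str]:
        out = []
        for g in genome.genes:
            bases = {(g.chrom, p) for p in g.union_positions}
            if bases & self.target_bases:
                out.append(g.symbol)
        return out

    def gene_coverage_manifest(self, genome: GenomeFixture) -> Dict[str, object]:
        cov: Dict[str, object] = {}
        for g in genome.genes:
            bases = {(g.chrom, p) for p in g.union_positions}
            targeted = bases & self.target_bases
            masked = targeted & self.mask_bases
            cov[g.symbol] = {
                "exon_union_bases": len(bases),
                "targeted_bases": len(targeted),
                "targeted_masked_bases": len(masked),
                "coverage_fraction": len(targeted) / len(bases),
                "effective_coverage_fraction": (len(targeted) - len(masked))
                / len(bases),
            }
        return cov

    def exon_coverage_manifest(self, genome: GenomeFixture) -> Dict[str, List[int]]:
        rows: Dict[str, List[int]] = {}
        for g in genome.genes:
            for t in g.transcripts:
                for ordinal, (s, e) in enumerate(sorted(t.exons), 1):
                    bases = {(g.chrom, p) for p in range(s, e + 1)}
                    covered = bases & self.target_bases
                    masked = covered & self.mask_bases
                    rows[f"{t.tid}|{ordinal}"] = [len(covered), len(masked)]
        return rows


@dataclass
class VariantFixture:
    source: str  # CLINVAR / COSMIC
    record_id: str
    gene_symbol: str
    chrom: str
    start: int
    end: int
    classification: str
    positive: Optional[int] = None
    tested: Optional[int] = None

    @property
    def key(self) -> str:
        return f"{self.source}:{self.record_id}"

    @property
    def span(self) -> Set[Base]:
        return {(self.chrom, p) for p in range(self.start, self.end + 1)}


# ---------------------------------------------------------------------------
# genome


def make_genome(
    outdir: str,
    seed: int = 1,
    n_genes: int = 30,
    n_chroms: int = 2,
    size_per_chrom: int = 100_000,
) -> GenomeFixture:
    """Generate the toy annotation and write it in GTF, GFF3 and UCSC dialects."""
    if n_genes < 1:
        raise GenerationError("n_genes must be >= 1")
    if size_per_chrom < 1000:
        raise GenerationError("chromosomes must be >= 1 kb")
    rng = np.random.default_rng([seed, 101])
    chroms = [f"chr{i + 1}" for i in range(n_chroms)]
    cursors = {c: 1000 for c in chroms}
    width = len(str(n_genes))
    genes: List[GeneFixture] = []

    i = 0
    while i < n_genes:
        chrom = chroms[i % n_chroms]
        interleave = n_genes >= 6 and i == 2  # plant one interleaved pair
        noncoding = i == n_genes - 1  # plant one non-coding gene
        if interleave and i + 1 < n_genes:
            sym_a = f"GENE{i + 1:0{width}d}"
            sym_b = f"GENE{i + 2:0{width}d}"
            pair, cursors[chrom] = _interleaved_pair(
                rng, chrom, cursors[chrom], sym_a, sym_b, i
            )
            genes.extend(pair)
            i += 2
            continue
        symbol = f"GENE{i + 1:0{width}d}"
        gene, cursors[chrom] = _make_gene(
            rng, chrom, cursors[chrom], symbol, i, noncoding=noncoding
        )
        genes.append(gene)
        i += 1

    for c, cur in cursors.items():
        if cur > size_per_chrom - 500:
            raise GenerationError(
                f"genes exceed chromosome {c}: cursor {cur} > {size_per_chrom - 500}"
            )

    genome = GenomeFixture(genes=genes, chrom_sizes={c: size_per_chrom for c in chroms})
    genome.gtf_path = os.path.join(outdir, "genome.gtf")
    genome.gff3_path = os.path.join(outdir, "genome.gff3")
    genome.ucsc_path = os.path.join(outdir, "genome.ucsc.txt")
    _write_gtf(genome, genome.gtf_path)
    _write_gff3(genome, genome.gff3_path)
    _write_ucsc(genome, genome.ucsc_path)
    return genome


def _make_gene(
    rng: np.random.Generator,
    chrom: str,
    cursor: int,
    symbol: str,
    idx: int,
    noncoding: bool = False,
) -> Tuple[GeneFixture, int]:
    n_exons = int(rng.integers(1, 11))
    start = cursor + int(rng.integers(200, 800))
    exons: List[Tuple[int, int]] = []
    gaps: List[int] = []
    pos = start
    for k in range(n_exons):
        length = int(rng.integers(50, 301))
        exons.append((pos, pos + length - 1))
        gap = int(rng.integers(50, 501))
        gaps.append(gap)
        pos = pos + length + gap
    transcripts = _make_transcripts(rng, symbol, idx, exons, gaps, noncoding)
    return GeneFixture(symbol=symbol, chrom=chrom, transcripts=transcripts), exons[-1][1]


def _interleaved_pair(
    rng: np.random.Generator,
    chrom: str,
    cursor: int,
    sym_a: str,
    sym_b: str,
    idx: int,
) -> Tuple[List[GeneFixture], int]:
    """Two genes whose genomic spans interleave but whose exons never overlap."""
    start = cursor + int(rng.integers(200, 800))
    pos = start
    ex_a: List[Tuple[int, int]] = []
    ex_b: List[Tuple[int, int]] = []
    for _ in range(3):
        for target in (ex_a, ex_b):
            length = int(rng.integers(60, 200))
            target.append((pos, pos + length - 1))
            pos += length + int(rng.integers(60, 200))
    gene_a = GeneFixture(
        symbol=sym_a,
        chrom=chrom,
        transcripts=_make_transcripts(rng, sym_a, idx, ex_a, [60] * 3, False),
    )
    gene_b = GeneFixture(
        symbol=sym_b,
        chrom=chrom,
        transcripts=_make_transcripts(rng, sym_b, idx + 1, ex_b, [60] * 3, False),
    )
    return [gene_a, gene_b], pos


def _make_transcripts(
    rng: np.random.Generator,
    symbol: str,
    idx: int,
    exons: List[Tuple[int, int]],
    gaps: List[int],
    noncoding: bool,
) -> List[TranscriptFixture]:
    prefix = "NR" if noncoding else "NM"
    n_tx = int(rng.integers(1, 4))
    txs: List[TranscriptFixture] = []
    for t in range(n_tx):
        if t == 0:
            tx_exons = list(exons)
        else:
            a = int(rng.integers(0, len(exons)))
            b = int(rng.integers(a + 1, len(exons) + 1))
            tx_exons = [list(x) for x in exons[a:b]]
            # extend the first exon upstream into the intron to give this
            # transcript a private exon-union contribution
            if a > 0:
                d = int(rng.integers(10, max(11, min(40, gaps[a - 1] // 2))))
                tx_exons[0][0] -= d
            tx_exons = [tuple(x) for x in tx_exons]
        cds = None
        if not noncoding:
            first_s, first_e = tx_exons[0]
            last_s, last_e = tx_exons[-1]
            off1 = int(rng.integers(0, max(1, (first_e - first_s) // 2)))
            off2 = int(rng.integers(0, max(1, (last_e - last_s) // 2)))
            cs, ce = first_s + off1, last_e - off2
            if cs <= ce:
                cds = (cs, ce)
        txs.append(
            TranscriptFixture(tid=f"{prefix}_{idx + 1:03d}{t + 1:02d}", exons=tx_exons, cds=cds)
        )
    return txs


# -- annotation writers ------------------------------------------------------


def _transcript_cds_pieces(t: TranscriptFixture) -> List[Tuple[int, int]]:
    if t.cds is None:
        return []
    cs, ce = t.cds
    out = []
    for s, e in t.exons:
        lo, hi = max(s, cs), min(e, ce)
        if lo <= hi:
            out.append((lo, hi))
    return out


def _write_gtf(genome: GenomeFixture, path: str) -> None:
    with open(path, "w") as fh:
        for g in sorted(genome.genes, key=lambda g: (g.chrom, min(s for t in g.transcripts for s, _ in t.exons))):
            g_start = min(s for t in g.transcripts for s, _ in t.exons)
            g_end = max(e for t in g.transcripts for _, e in t.exons)
            attrs = f'gene_id "{g.symbol}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tsynth\tgene\t{g_start}\t{g_end}\t.\t+\t.\t{attrs}\n"
            )
            for t in g.transcripts:
                t_attrs = (
                    f'gene_id "{g.symbol}"; transcript_id "{t.tid}"; '
                    f'gene_name "{g.symbol}";'
                )
                fh.write(
                    f"{g.chrom}\tsynth\ttranscript\t{t.exons[0][0]}\t"
                    f"{t.exons[-1][1]}\t.\t+\t.\t{t_attrs}\n"
                )
                for n, (s, e) in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.chrom}\tsynth\texon\t{s}\t{e}\t.\t+\t.\t"
                        f'{t_attrs} exon_number "{n}";\n'
                    )
                for s, e in _transcript_cds_pieces(t):
                    fh.write(
                        f"{g.chrom}\tsynth\tCDS\t{s}\t{e}\t.\t+\t0\t{t_attrs}\n"
                    )


def _write_gff3(genome: GenomeFixture, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genome.genes, key=lambda g: (g.chrom, min(s for t in g.transcripts for s, _ in t.exons))):
            g_start = min(s for t in g.transcripts for s, _ in t.exons)
            g_end = max(e for t in g.transcripts for _, e in t.exons)
            gid = f"gene:{g.symbol}"
            fh.write(
                f"{g.chrom}\tsynth\tgene\t{g_start}\t{g_end}\t.\t+\t.\t"
                f"ID={gid};Name={g.symbol}\n"
            )
            for t in g.transcripts:
                kind = "mRNA" if t.cds else "transcript"
                fh.write(
                    f"{g.chrom}\tsynth\t{kind}\t{t.exons[0][0]}\t{t.exons[-1][1]}"
                    f"\t.\t+\t.\tID={t.tid};Parent={gid}\n"
                )
                for n, (s, e) in enumerate(t.exons, 1):
                    fh.write(
                        f"{g.chrom}\tsynth\texon\t{s}\t{e}\t.\t+\t.\t"
                        f"ID={t.tid}.exon.{n};Parent={t.tid}\n"
                    )
                for n, (s, e) in enumerate(_transcript_cds_pieces(t), 1):
                    fh.write(
                        f"{g.chrom}\tsynth\tCDS\t{s}\t{e}\t.\t+\t0\t"
                        f"ID={t.tid}.cds.{n};Parent={t.tid}\n"
                    )


def _write_ucsc(genome: GenomeFixture, path: str) -> None:
    """refGene-table dialect: headerless, leading bin column, 0-based starts,
    trailing commas in exonStarts/exonEnds."""
    with open(path, "w") as fh:
        for g in genome.genes:
            for t in g.transcripts:
                tx_start0 = t.exons[0][0] - 1
                tx_end = t.exons[-1][1]
                if t.cds:
                    cds_start0, cds_end = t.cds[0] - 1, t.cds[1]
                else:
                    cds_start0 = cds_end = tx_end  # refGene convention: empty CDS
                starts = "".join(f"{s - 1}," for s, _ in t.exons)
                ends = "".join(f"{e}," for _, e in t.exons)
                fields = [
                    "0",  # bin
                    t.tid,
                    g.chrom,
                    "+",
                    str(tx_start0),
                    str(tx_end),
                    str(cds_start0),
                    str(cds_end),
                    str(len(t.exons)),
                    starts,
                    ends,
                    "0",
                    g.symbol,
                    "cmpl" if t.cds else "none",
                    "cmpl" if t.cds else "none",
                    ",".join("0" for _ in t.exons) + ",",
                ]
                fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# panels


DEFAULT_PANEL_PLANS: Dict[str, Dict[str, object]] = {
    "ALPHA": {
        "coverage": {
            "GENE01": 0.25,
            "GENE02": 0.50,
            "GENE03": 0.90,
            "GENE04": 0.40,
            "GENE05": 1.00,
            "GENE06": 0.75,
            "GENE07": 0.60,
            "GENE08": 0.10,
            "GENE10": 0.30,
            "GENE12": 0.95,
            "GENE13": 0.20,
            "GENE14": 0.55,
            "GENE15": 0.65,
            "GENE16": 0.35,
            "GENE17": 0.85,
            "GENE18": 0.45,
            "GENE30": 0.70,
        },
        "mask": {"GENE05": "full", "GENE01": 0.25, "GENE10": 0.5},
    },
    "BETA": {
        "coverage": {
            "GENE02": 0.60,
            "GENE03": 0.45,
            "GENE05": 0.80,
            "GENE06": 0.30,
            "GENE07": 0.70,
            "GENE19": 0.50,
            "GENE20": 0.90,
            "GENE21": 0.40,
            "GENE22": 1.00,
            "GENE23": 0.15,
            "GENE24": 0.50,
            "GENE30": 0.35,
        },
        "mask": None,  # this panel does not use a mask file
    },
}

# advertised list for ALPHA: three confirmed targets (one fully masked),
# two advertised genes the panel does not touch
DEFAULT_ADVERTISED = {
    "ALPHA": ["GENE03", "GENE05", "GENE07", "GENE09", "GENE11"],
}


def make_panel(
    genome: GenomeFixture,
    name: str,
    coverage_spec: Dict[str, float],
    mask_plan: Optional[Dict[str, object]],
    outdir: str,
    seed: int = 1,
    n_comments: int = 3,
) -> PanelFixture:
    """Realize a panel from per-gene coverage fractions; write messy BEDs.

    For each gene, the requested fraction of its exon-union bases (taken
    from the start of the gene) becomes target bases; short intergenic
    padding flanks are added that never touch any gene's exons, so
    realized per-gene counts match the chosen base sets exactly.  The mask
    plan maps gene -> ``"full"`` (mask every targeted base; the
    fully-masked-target pattern) or a fraction of targeted bases to mask.
    """
    rng = np.random.default_rng([seed, 211, _name_seed(name)])
    all_exonic = genome.all_exon_bases
    target: Set[Base] = set()
    per_gene_target: Dict[str, Set[Base]] = {}
    for symbol in sorted(coverage_spec):
        frac = coverage_spec[symbol]
        if not (0.0 <= frac <= 1.0):
            raise GenerationError(f"coverage fraction {frac} for {symbol} not in [0,1]")
        if frac == 0.0:
            continue
        g = genome.gene(symbol)
        positions = sorted(g.union_positions)
        k = len(positions) if frac == 1.0 else max(1, round(frac * len(positions)))
        chosen = {(g.chrom, p) for p in positions[:k]}
        per_gene_target[symbol] = chosen
        target |= chosen

    # non-exonic padding around target runs (panels tile past exon edges)
    padding: Set[Base] = set()
    for chrom, s, e in _runs(target):
        if rng.random() < 0.5:
            flank = int(rng.integers(3, 9))
            for p in list(range(s - flank, s)) + list(range(e + 1, e + flank + 1)):
                if p >= 1 and (chrom, p) not in all_exonic:
                    padding.add((chrom, p))
    target |= padding

    mask: Set[Base] = set()
    has_mask = mask_plan is not None
    if mask_plan:
        for symbol, plan in sorted(mask_plan.items()):
            gene_target = sorted(per_gene_target.get(symbol, ()))
            if not gene_target:
                raise GenerationError(f"mask plan for untargeted gene {symbol}")
            if plan == "full":
                mask.update(gene_target)
            else:
                m = max(1, round(float(plan) * len(gene_target)))
                mask.update(gene_target[:m])
        # a few masked positions outside any exon, as real mask files have
        for chrom, s, e in list(_runs(padding))[:3]:
            mask.add((chrom, s))

    target_bed = os.path.join(outdir, f"{name}.target.bed")
    records = _write_messy_bed(target, target_bed, rng, n_comments)
    mask_bed = ""
    if has_mask:
        mask_bed = os.path.join(outdir, f"{name}.mask.bed")
        _write_messy_bed(mask, mask_bed, rng, 1)
    return PanelFixture(
        name=name,
        target_bases=target,
        mask_bases=mask,
        target_bed=target_bed,
        mask_bed=mask_bed,
        record_count=records,
        comment_lines=n_comments,
    )


def _name_seed(name: str) -> int:
    return sum(ord(c) for c in name) % (2**16)


def _runs(bases: Set[Base]) -> List[Tuple[str, int, int]]:
    """Maximal runs of consecutive bases, per chromosome (brute force)."""
    out: List[Tuple[str, int, int]] = []
    by_chrom: Dict[str, List[int]] = {}
    for chrom, p in bases:
        by_chrom.setdefault(chrom, []).append(p)
    for chrom in sorted(by_chrom):
        pos = sorted(by_chrom[chrom])
        start = prev = pos[0]
        for p in pos[1:]:
            if p == prev + 1:
                prev = p
                continue
            out.append((chrom, start, prev))
            start = prev = p
        out.append((chrom, start, prev))
    return out


def _write_messy_bed(
    bases: Set[Base], path: str, rng: np.random.Generator, n_comments: int
) -> int:
    """Write a base set as BED with realistic mess: adjacent fragments,
    duplicates, shuffled order, comment/track lines.  Returns data-line count."""
    records: List[Tuple[str, int, int]] = []
    for chrom, s, e in _runs(bases):
        if e - s >= 5 and rng.random() < 0.3:  # split into adjacent fragments
            cut = int(rng.integers(s + 1, e))
            records.append((chrom, s - 1, cut))
            records.append((chrom, cut, e))
        else:
            records.append((chrom, s - 1, e))
        if rng.random() < 0.15:
            records.append(records[-1])  # duplicate record
    order = rng.permutation(len(records))
    comments = [
        'track name="synthetic panel" description="fixture"',
        "# synthetic fixture file",
        "browser position chr1:1-100000",
    ]
    with open(path, "w") as fh:
        for c in comments[:n_comments]:
            fh.write(c + "\n")
        for i in order:
            chrom, s0, e0 = records[i]
            fh.write(f"{chrom}\t{s0}\t{e0}\n")
    return len(records)


# ---------------------------------------------------------------------------
# variants


def make_variants(
    genome: GenomeFixture,
    panels: Sequence[PanelFixture],
    outdir: str,
    seed: int = 1,
    n_clinvar: int = 100,
    n_cosmic: int = 200,
) -> Tuple[List[VariantFixture], List[VariantFixture], Dict[str, object]]:
    """Write ClinVar- and CMC-dialect tables plus the variant manifest fragment.

    Plants SNVs, multi-base indels straddling target boundaries (where the
    containment and any-overlap rules disagree), masked-position variants,
    benign/conflicting/tier-Other/wrong-assembly decoys, and rows the
    readers must skip (zero tested samples, unparseable coordinates).
    """
    rng = np.random.default_rng([seed, 307])
    ref = panels[0] if panels else None

    n_cv_keep = min(37, n_clinvar)
    n_cmc_keep = min(120, n_cosmic)
    clinvar = _plant_variants(
        genome, ref, rng, n_cv_keep, source="CLINVAR", id_base=500_000
    )
    cosmic = _plant_variants(
        genome, ref, rng, n_cmc_keep, source="COSMIC", id_base=900_000
    )

    _write_clinvar(clinvar, genome, rng, n_clinvar, os.path.join(outdir, "clinvar.tsv"))
    _write_cmc(cosmic, genome, rng, n_cosmic, os.path.join(outdir, "cmc.tsv"))

    fragment: Dict[str, object] = {
        "clinvar": {
            "total_rows": n_clinvar,
            "retained_ids": [v.record_id for v in clinvar],
        },
        "cosmic": {
            "total_rows": n_cosmic,
            "retained_ids": [v.record_id for v in cosmic],
            "frequencies": {v.record_id: [v.positive, v.tested] for v in cosmic},
        },
        "variant_labels": {},
        "rates": {},
    }
    for panel in panels:
        labels: Dict[str, object] = {}
        for v in clinvar + cosmic:
            labels[v.key] = _label(v, panel)
        fragment["variant_labels"][panel.name] = labels
        fragment["rates"][panel.name] = _rates(genome, panel, cosmic)
    return clinvar, cosmic, fragment


def _label(v: VariantFixture, panel: PanelFixture) -> Dict[str, bool]:
    span = v.span
    contained = span <= panel.target_bases
    any_overlap = bool(span & panel.target_bases)
    masked = bool(span & panel.mask_bases)
    return {
        "targeted_contained": contained,
        "targeted_any": any_overlap,
        "masked": masked,
        "detectable_contained": contained and not masked,
        "detectable_any": any_overlap and not masked,
    }


def _rates(
    genome: GenomeFixture, panel: PanelFixture, cosmic: List[VariantFixture]
) -> Dict[str, Dict[str, float]]:
    target_genes = set(panel.target_genes(genome))
    out: Dict[str, Dict[str, float]] = {}
    for rule in OVERLAP_RULES:
        rates: Dict[str, float] = {}
        for setting in RATE_SETTINGS:
            scope_target = setting.startswith("target_genes")
            use_mask = setting.endswith("_masked")
            freqs = []
            for v in cosmic:
                if scope_target and v.gene_symbol not in target_genes:
                    continue
                lab = _label(v, panel)
                targeted = lab["targeted_contained" if rule == "contained" else "targeted_any"]
                missed = (not targeted) or (use_mask and lab["masked"])
                if missed:
                    freqs.append(v.positive / v.tested)
            rates[setting] = math.fsum(freqs)
        out[rule] = rates
    return out


def _plant_variants(
    genome: GenomeFixture,
    ref_panel: Optional[PanelFixture],
    rng: np.random.Generator,
    n_keep: int,
    source: str,
    id_base: int,
) -> List[VariantFixture]:
    sig_cycle = ["Pathogenic", "Likely pathogenic", "Pathogenic/Likely pathogenic"]
    tier_cycle = ["1", "2", "3"]
    boundary_positions = (
        _boundary_spans(genome, ref_panel) if ref_panel is not None else []
    )
    out: List[VariantFixture] = []
    for i in range(n_keep):
        rid = str(id_base + i)
        if boundary_positions and i % 9 == 4:
            # multi-base span straddling a target-region edge: targeted
            # under any-overlap, not under containment
            chrom, s, e, symbol = boundary_positions[i % len(boundary_positions)]
        else:
            g = genome.genes[int(rng.integers(0, len(genome.genes)))]
            positions = sorted(g.union_positions)
            p = positions[int(rng.integers(0, len(positions)))]
            span_len = 1 if rng.random() < 0.7 else int(rng.integers(2, 11))
            chrom, s, e, symbol = g.chrom, p, p + span_len - 1, g.symbol
        if i == n_keep - 1:
            symbol = "GENEX"  # symbol absent from the annotation
        if source == "CLINVAR":
            out.append(
                VariantFixture(
                    source=source,
                    record_id=rid,
                    gene_symbol=symbol,
                    chrom=chrom,
                    start=s,
                    end=e,
                    classification=sig_cycle[i % 3],
                )
            )
        else:
            tested = int(rng.integers(500, 2001))
            positive = int(rng.integers(1, 31))
            out.append(
                VariantFixture(
                    source=source,
                    record_id=f"COSV{rid}",
                    gene_symbol=symbol,
                    chrom=chrom,
                    start=s,
                    end=e,
                    classification=tier_cycle[i % 3],
                    positive=positive,
                    tested=tested,
                )
            )
    return out


def _boundary_spans(
    genome: GenomeFixture, panel: PanelFixture
) -> List[Tuple[str, int, int, str]]:
    """Spans [p, p+3] whose first base is targeted and whose tail exits the
    target set while remaining exonic."""
    out = []
    for g in genome.genes:
        union = g.union_positions
        for chrom, p in sorted(panel.target_bases):
            if chrom != g.chrom or p not in union:
                continue
            tail = [p + 1, p + 2, p + 3]
            if all(q in union and (chrom, q) not in panel.target_bases for q in tail):
                out.append((chrom, p, p + 3, g.symbol))
                break
    return out


def _write_clinvar(
    keep: List[VariantFixture],
    genome: GenomeFixture,
    rng: np.random.Generator,
    n_total: int,
    path: str,
) -> None:
    header = [
        "#AlleleID",
        "Type",
        "Name",
        "GeneSymbol",
        "ClinicalSignificance",
        "Assembly",
        "Chromosome",
        "Start",
        "Stop",
        "VariationID",
    ]
    rows: List[List[str]] = []
    for v in keep:
        rows.append(_clinvar_row(v, v.classification, "GRCh37"))
    n_decoy = n_total - len(keep)
    decoy_sigs = (
        ["Benign"] * 25
        + ["Conflicting interpretations of pathogenicity"] * 13
        + ["Likely pathogenic; Benign"] * 5
    )
    wrong_assembly = n_decoy - len(decoy_sigs)
    if wrong_assembly < 0:
        decoy_sigs = decoy_sigs[:n_decoy]
        wrong_assembly = 0
    for j, sig in enumerate(decoy_sigs):
        g = genome.genes[int(rng.integers(0, len(genome.genes)))]
        p = sorted(g.union_positions)[0] + j
        decoy = VariantFixture(
            source="CLINVAR",
            record_id=str(700_000 + j),
            gene_symbol=g.symbol,
            chrom=g.chrom,
            start=p,
            end=p,
            classification=sig,
        )
        rows.append(_clinvar_row(decoy, sig, "GRCh37"))
    for j in range(wrong_assembly):
        v = keep[j % len(keep)]
        rows.append(_clinvar_row(v, v.classification, "GRCh38"))
    order = rng.permutation(len(rows))
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i in order:
            fh.write("\t".join(rows[i]) + "\n")


def _clinvar_row(v: VariantFixture, sig: str, assembly: str) -> List[str]:
    chrom_bare = v.chrom[3:] if v.chrom.startswith("chr") else v.chrom
    start = v.start if assembly == "GRCh37" else v.start + 1000
    return [
        f"A{v.record_id}",
        "single nucleotide variant" if v.end == v.start else "Deletion",
        f"{v.gene_symbol}:c.{v.start}A>G",
        v.gene_symbol,
        sig,
        assembly,
        chrom_bare,
        str(start),
        str(start + (v.end - v.start)),
        v.record_id,
    ]


def _write_cmc(
    keep: List[VariantFixture],
    genome: GenomeFixture,
    rng: np.random.Generator,
    n_total: int,
    path: str,
) -> None:
    header = [
        "GENE_NAME",
        "GENOMIC_MUTATION_ID",
        "MUTATION_AA",
        "Mutation genome position GRCh37",
        "MUTATION_SIGNIFICANCE_TIER",
        "COSMIC_SAMPLE_MUTATED",
        "COSMIC_SAMPLE_TESTED",
    ]
    rows: List[List[str]] = []
    for v in keep:
        rows.append(_cmc_row(v, position=_cmc_pos(v)))
    n_decoy = n_total - len(keep)
    n_other = min(60, max(0, n_decoy - 20))
    n_zero_tested = min(10, max(0, n_decoy - n_other - 10))
    n_badpos = n_decoy - n_other - n_zero_tested
    j = 0
    for _ in range(n_other):
        v = _random_decoy(genome, rng, j, tier="Other")
        rows.append(_cmc_row(v, position=_cmc_pos(v)))
        j += 1
    for _ in range(n_zero_tested):
        v = _random_decoy(genome, rng, j, tier="1", tested=0)
        rows.append(_cmc_row(v, position=_cmc_pos(v)))
        j += 1
    for _ in range(n_badpos):
        v = _random_decoy(genome, rng, j, tier="1")
        rows.append(_cmc_row(v, position="?:?-?"))
        j += 1
    order = rng.permutation(len(rows))
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for i in order:
            fh.write("\t".join(rows[i]) + "\n")


def _cmc_pos(v: VariantFixture) -> str:
    chrom_bare = v.chrom[3:] if v.chrom.startswith("chr") else v.chrom
    return f"{chrom_bare}:{v.start}-{v.end}"


def _random_decoy(
    genome: GenomeFixture,
    rng: np.random.Generator,
    j: int,
    tier: str,
    tested: int = 1000,
) -> VariantFixture:
    g = genome.genes[int(rng.integers(0, len(genome.genes)))]
    p = sorted(g.union_positions)[0] + j % 40
    return VariantFixture(
        source="COSMIC",
        record_id=f"COSV8{j:05d}",
        gene_symbol=g.symbol,
        chrom=g.chrom,
        start=p,
        end=p,
        classification=tier,
        positive=1,
        tested=tested,
    )


def _cmc_row(v: VariantFixture, position: str) -> List[str]:
    return [
        v.gene_symbol,
        v.record_id,
        "p.V600E",
        position,
        v.classification,
        str(v.positive),
        str(v.tested),
    ]


# ---------------------------------------------------------------------------
# the full bundle


@dataclass
class FixtureBundle:
    outdir: str
    genome: GenomeFixture
    panels: Dict[str, PanelFixture]
    clinvar: List[VariantFixture]
    cosmic: List[VariantFixture]
    manifest: Dict[str, object]
    advertised_paths: Dict[str, str] = field(default_factory=dict)

    @property
    def manifest_path(self) -> str:
        return os.path.join(self.outdir, "manifest.json")


def make_bundle(
    outdir: str,
    seed: int = 1,
    n_genes: int = 30,
    n_chroms: int = 2,
    size_per_chrom: int = 100_000,
    n_clinvar: int = 100,
    n_cosmic: int = 200,
    panel_plans: Optional[Dict[str, Dict[str, object]]] = None,
    advertised: Optional[Dict[str, List[str]]] = None,
) -> FixtureBundle:
    """Generate the complete fixture study into *outdir* and write manifest.json."""
    os.makedirs(outdir, exist_ok=True)
    genome = make_genome(
        outdir, seed=seed, n_genes=n_genes, n_chroms=n_chroms,
        size_per_chrom=size_per_chrom,
    )
    plans = panel_plans if panel_plans is not None else DEFAULT_PANEL_PLANS
    adv = advertised if advertised is not None else DEFAULT_ADVERTISED
    symbols = {g.symbol for g in genome.genes}

    panels: Dict[str, PanelFixture] = {}
    manifest: Dict[str, object] = {
        "seed": seed,
        "params": {
            "n_genes": n_genes,
            "n_chroms": n_chroms,
            "size_per_chrom": size_per_chrom,
            "n_clinvar": n_clinvar,
            "n_cosmic": n_cosmic,
        },
    }
    manifest.update(genome.manifest_fragment())
    manifest["panels"] = {}
    for name, plan in plans.items():
        coverage = {s: f for s, f in plan["coverage"].items() if s in symbols}
        panel = make_panel(
            genome, name, coverage, plan.get("mask"), outdir, seed=seed
        )
        panels[name] = panel
        manifest["panels"][name] = {
            "target_genes": panel.target_genes(genome),
            "gene_coverage": panel.gene_coverage_manifest(genome),
            "exon_coverage": panel.exon_coverage_manifest(genome),
            "record_count": panel.record_count,
            "comment_lines": panel.comment_lines,
            "has_mask": bool(panel.mask_bed),
        }

    clinvar, cosmic, fragment = make_variants(
        genome, list(panels.values()), outdir, seed=seed,
        n_clinvar=n_clinvar, n_cosmic=n_cosmic,
    )
    manifest.update(fragment)

    advertised_paths: Dict[str, str] = {}
    manifest["advertised"] = {}
    for name, gene_list in adv.items():
        if name not in panels:
            continue
        path = os.path.join(outdir, f"advertised.{name}.txt")
        with open(path, "w") as fh:
            fh.write("\n".join(gene_list) + "\n")
        advertised_paths[name] = path
        targets = set(panels[name].target_genes(genome))
        known = [s for s in gene_list if s in symbols]
        cov = manifest["panels"][name]["gene_coverage"]
        fully_masked = sorted(
            s
            for s in (set(known) & targets)
            if cov[s]["targeted_bases"] > 0
            and cov[s]["targeted_masked_bases"] == cov[s]["targeted_bases"]
        )
        manifest["advertised"][name] = {
            "genes": gene_list,
            "expected": {
                "advertised_not_detected": sorted(set(known) - targets),
                "detected_not_advertised": sorted(targets - set(known)),
                "fully_masked_targets": fully_masked,
                "unknown_advertised": sorted(set(gene_list) - symbols),
            },
        }

    bundle = FixtureBundle(
        outdir=outdir,
        genome=genome,
        panels=panels,
        clinvar=clinvar,
        cosmic=cosmic,
        manifest=manifest,
        advertised_paths=advertised_paths,
    )
    with open(bundle.manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return bundle
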