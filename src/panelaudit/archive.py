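"""Persistent analysis archives: one zip container per panel analysis.

The archive holds versioned tabular payloads (TSV) plus a JSON manifest
with per-payload SHA-256 checksums and provenance strings.  Loading
verifies checksums and the format version; a mismatch raises
:class:`ArchiveError` rather than silently returning a partial result.

Payload bytes are a pure function of the analysis content: entries are
written in a fixed order with a fixed zip timestamp, so two runs on
identical inputs produce byte-identical payload sections.  The wall-clock
creation time lives only in the manifest's ``created`` field, which is
excluded from comparisons.
"""

from __future__ import annotations

import hashlib
import io
import json
import zipfile
from datetime import datetime, timezone
from typing import Dict, List

from . import __version__
from .engine import (
    ClassifiedVariant,
    ExonCoverageRow,
    GeneCoverageStat,
    NoncoveredRateSummary,
    PanelAnalysis,
)
from .intervals import GenomicInterval
from .variants import VariantRecord

FORMAT_VERSION = 1
ARCHIVE_SUFFIX = ".pau.zip"
_ZIP_DATE = (1980, 1, 1, 0, 0, 0)  # fixed: archives must be run-independent


class ArchiveError(RuntimeError):
    """Archive is corrupted, incomplete, or of an incompatible version."""


_GENE_COLS = [
    "gene_symbol",
    "exon_union_bases",
    "targeted_bases",
    "targeted_masked_bases",
    "clinvar_total",
    "clinvar_targeted",
    "clinvar_targeted_masked",
    "cosmic_total",
    "cosmic_targeted",
    "cosmic_targeted_masked",
]

_EXON_COLS = [
    "gene_symbol",
    "transcript_id",
    "exon_number",
    "chrom",
    "start",
    "end",
    "covered_bases",
    "masked_covered_bases",
]

_VARIANT_COLS = [
    "source",
    "record_id",
    "gene_symbol",
    "chrom",
    "start",
    "end",
    "classification",
    "positive_samples",
    "tested_samples",
    "hgvs_label",
    "targeted",
    "masked",
    "symbol_unmatched",
]


def _tsv(header: List[str], rows: List[List[str]]) -> bytes:
    lines = ["\t".join(header)]
    lines.extend("\t".join(r) for r in rows)
    return ("\n".join(lines) + "\n").encode()


def _gene_rows(stats: List[GeneCoverageStat]) -> List[List[str]]:
    return [[str(getattr(g, c)) for c in _GENE_COLS] for g in stats]


def _exon_rows(rows: List[ExonCoverageRow]) -> List[List[str]]:
    return [
        [
            r.gene_symbol,
            r.transcript_id,
            str(r.exon_number),
            r.exon_interval.chrom,
            str(r.exon_interval.start),
            str(r.exon_interval.end),
            str(r.covered_bases),
            str(r.masked_covered_bases),
        ]
        for r in rows
    ]


def _variant_rows(cvs: List[ClassifiedVariant]) -> List[List[str]]:
    out = []
    for cv in cvs:
        r = cv.record
        out.append(
            [
                r.source,
                r.record_id,
                r.gene_symbol,
                r.chrom,
                str(r.start),
                str(r.end),
                r.classification,
                "" if r.positive_samples is None else str(r.positive_samples),
                "" if r.tested_samples is None else str(r.tested_samples),
                r.hgvs_label,
                str(int(cv.targeted)),
                str(int(cv.masked)),
                str(int(cv.symbol_unmatched)),
            ]
        )
    return out


def payloads(analysis: PanelAnalysis) -> Dict[str, bytes]:
    """The deterministic payload entries of an archive, by entry name."""
    meta = {
        "panel_name": analysis.panel_name,
        "panel_sources": list(analysis.panel_sources),
        "target_gene_set": sorted(analysis.target_gene_set),
        "summary": analysis.summary.as_dict(),
        "db_versions": dict(sorted(analysis.db_versions.items())),
        "overlap_rule": analysis.overlap_rule,
        "cds_only": analysis.cds_only,
    }
    return {
        "analysis.json": json.dumps(meta, sort_keys=True, indent=1).encode(),
        "gene_stats.tsv": _tsv(_GENE_COLS, _gene_rows(analysis.gene_stats)),
        "exon_table.tsv": _tsv(_EXON_COLS, _exon_rows(analysis.exon_table)),
        "variants.tsv": _tsv(_VARIANT_COLS, _variant_rows(analysis.classified_variants)),
    }


def write_archive(analysis: PanelAnalysis, path: str) -> None:
    entries = payloads(analysis)
    manifest = {
        "format": "panelaudit-archive",
        "format_version": FORMAT_VERSION,
        "tool_version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
        "checksums": {
            name: hashlib.sha256(data).hexdigest() for name, data in entries.items()
        },
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(entries):
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            zf.writestr(info, entries[name])
        info = zipfile.ZipInfo("manifest.json", date_time=_ZIP_DATE)
        info.compress_type = zipfile.ZIP_DEFLATED
        zf.writestr(info, json.dumps(manifest, sort_keys=True, indent=1).encode())


def read_archive(path: str) -> PanelAnalysis:
    try:
        with zipfile.ZipFile(path) as zf:
            names = set(zf.namelist())
            if "manifest.json" not in names:
                raise ArchiveError(f"{path}: not a panel archive (no manifest)")
            manifest = json.loads(zf.read("manifest.json"))
            if manifest.get("format") != "panelaudit-archive":
                raise ArchiveError(f"{path}: unrecognized archive format")
            if manifest.get("format_version") != FORMAT_VERSION:
                raise ArchiveError(
                    f"{path}: archive format version "
                    f"{manifest.get('format_version')} is incompatible with "
                    f"this tool (expected {FORMAT_VERSION})"
                )
            data: Dict[str, bytes] = {}
            for name, checksum in manifest["checksums"].items():
                if name not in names:
                    raise ArchiveError(f"{path}: missing payload {name!r}")
                raw = zf.read(name)
                if hashlib.sha256(raw).hexdigest() != checksum:
                    raise ArchiveError(f"{path}: checksum mismatch for {name!r}")
                data[name] = raw
    except zipfile.BadZipFile as exc:
        raise ArchiveError(f"{path}: not a readable zip container: {exc}") from exc

    meta = json.loads(data["analysis.json"])

    gene_stats = [
        GeneCoverageStat(
            gene_symbol=row["gene_symbol"],
            **{c: int(row[c]) for c in _GENE_COLS[1:]},
        )
        for row in _parse_tsv(data["gene_stats.tsv"], _GENE_COLS)
    ]
    exon_table = [
        ExonCoverageRow(
            gene_symbol=row["gene_symbol"],
            transcript_id=row["transcript_id"],
            exon_number=int(row["exon_number"]),
            exon_interval=GenomicInterval(
                row["chrom"], int(row["start"]), int(row["end"])
            ),
            covered_bases=int(row["covered_bases"]),
            masked_covered_bases=int(row["masked_covered_bases"]),
        )
        for row in _parse_tsv(data["exon_table.tsv"], _EXON_COLS)
    ]
    variants = []
    for row in _parse_tsv(data["variants.tsv"], _VARIANT_COLS):
        rec = VariantRecord(
            source=row["source"],
            record_id=row["record_id"],
            gene_symbol=row["gene_symbol"],
            chrom=row["chrom"],
            start=int(row["start"]),
            end=int(row["end"]),
            classification=row["classification"],
            positive_samples=int(row["positive_samples"])
            if row["positive_samples"]
            else None,
            tested_samples=int(row["tested_samples"])
            if row["tested_samples"]
            else None,
            hgvs_label=row["hgvs_label"],
        )
        variants.append(
            ClassifiedVariant(
                record=rec,
                targeted=bool(int(row["targeted"])),
                masked=bool(int(row["masked"])),
                symbol_unmatched=bool(int(row["symbol_unmatched"])),
            )
        )

    return PanelAnalysis(
        panel_name=meta["panel_name"],
        panel_sources=tuple(meta["panel_sources"]),
        gene_stats=gene_stats,
        exon_table=exon_table,
        classified_variants=variants,
        target_gene_set=set(meta["target_gene_set"]),
        summary=NoncoveredRateSummary(**meta["summary"]),
        db_versions=meta["db_versions"],
        overlap_rule=meta["overlap_rule"],
        cds_only=meta["cds_only"],
    )


def _parse_tsv(raw: bytes, cols: List[str]) -> List[Dict[str, str]]:
    lines = raw.decode().splitlines()
    header = lines[0].split("\t")
    if header != cols:
        raise ArchiveError(f"unexpected payload columns: {header}")
    out = []
    for line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(cols):
            raise ArchiveError("payload row width mismatch")
        out.append(dict(zip(cols, fields)))
    return out
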