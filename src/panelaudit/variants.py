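"""Readers for curated mutation tables: ClinVar variant_summary and COSMIC CMC.

Both readers apply the source's relevance filter at parse time, so a
:class:`VariantRecord` by construction represents a clinically relevant
mutation:

* ClinVar rows are kept when the clinical-significance string (lowercased)
  contains ``"pathogenic"`` but neither ``"conflicting"`` nor ``"benign"``,
  on the requested assembly only.  The rule admits "Pathogenic", "Likely
  pathogenic" and "Pathogenic/Likely pathogenic" and conservatively drops
  compound or conflicting labels; it can be overridden via
  ``significance_filter``.
* CMC rows are kept for mutation-significance tiers 1-3; the positive
  sample proportion (mutated / tested samples) is carried along as the
  per-sample frequency used by the noncovered-mutation-rate estimate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Dict, List, Optional, Tuple

import pandas as pd

from .intervals import normalize_chrom

CLINVAR = "CLINVAR"
COSMIC = "COSMIC"


class VariantTableError(ValueError):
    """Schema problem in a variant table (missing/unusable required column)."""


@dataclass(frozen=True)
class VariantRecord:
    """One database mutation with its reference-allele span (1-based closed)."""

    source: str  # CLINVAR or COSMIC
    record_id: str
    gene_symbol: str
    chrom: str
    start: int
    end: int
    classification: str
    positive_samples: Optional[int] = None  # COSMIC only
    tested_samples: Optional[int] = None  # COSMIC only
    hgvs_label: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise VariantTableError(
                f"{self.source} {self.record_id}: end < start"
            )
        if (self.source == COSMIC) != (self.tested_samples is not None):
            raise VariantTableError(
                f"{self.source} {self.record_id}: sample counts present iff COSMIC"
            )

    @property
    def sample_frequency(self) -> Optional[float]:
        """Positive sample proportion in [0, 1]; None for ClinVar records."""
        if self.tested_samples is None:
            return None
        return self.positive_samples / self.tested_samples

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1


def default_pathogenic_filter(significance: str) -> bool:
    s = significance.lower()
    return "pathogenic" in s and "conflicting" not in s and "benign" not in s


@dataclass
class ReadReport:
    """Accounting of a reader run: retained + dropped + skipped = data rows."""

    total_rows: int = 0
    retained: int = 0
    dropped_filter: int = 0
    skipped_unusable: int = 0
    skip_reasons: Dict[str, int] = field(default_factory=dict)

    def skip(self, reason: str) -> None:
        self.skipped_unusable += 1
        self.skip_reasons[reason] = self.skip_reasons.get(reason, 0) + 1


_CLINVAR_COLS = {
    "record_id": "VariationID",
    "gene": "GeneSymbol",
    "significance": "ClinicalSignificance",
    "assembly": "Assembly",
    "chrom": "Chromosome",
    "start": "Start",
    "stop": "Stop",
}


def _require(df: pd.DataFrame, name: str) -> str:
    for col in df.columns:
        if col.lstrip("#").lower() == name.lower():
            return col
    raise VariantTableError(f"required column {name!r} missing from table")


def read_clinvar(
    path: str,
    assembly_filter: str = "GRCh37",
    chrom_style: str = "chr",
    significance_filter: Callable[[str], bool] = default_pathogenic_filter,
) -> Tuple[List[VariantRecord], ReadReport]:
    """Read a ClinVar variant_summary-dialect TSV, keeping (likely) pathogenic rows.

    Duplicate (VariationID, Assembly) pairs are deduplicated, first
    occurrence wins; coordinates are taken as 1-based inclusive as provided.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    cols = {k: _require(df, v) for k, v in _CLINVAR_COLS.items()}
    report = ReadReport(total_rows=len(df))
    records: List[VariantRecord] = []
    seen = set()
    name_col = next((c for c in df.columns if c.lower() == "name"), None)
    for row in df.to_dict("records"):
        get = lambda k: str(row[cols[k]])
        if get("assembly") != assembly_filter:
            report.dropped_filter += 1
            continue
        if not significance_filter(get("significance")):
            report.dropped_filter += 1
            continue
        key = (get("record_id"), get("assembly"))
        if key in seen:
            report.skip("duplicate (VariationID, Assembly)")
            continue
        seen.add(key)
        try:
            start, stop = int(get("start")), int(get("stop"))
        except ValueError:
            report.skip("non-integer coordinates")
            continue
        records.append(
            VariantRecord(
                source=CLINVAR,
                record_id=get("record_id"),
                gene_symbol=get("gene"),
                chrom=normalize_chrom(get("chrom"), chrom_style),
                start=start,
                end=stop,
                classification=get("significance"),
                hgvs_label=str(row[name_col]) if name_col else "",
            )
        )
    report.retained = len(records)
    return records, report


_POSITION_RE = re.compile(r"^(?:chr)?([\w.]+):(\d+)-(\d+)$")

_CMC_TIERS = {"1", "2", "3"}


def read_cmc(
    path: str,
    chrom_style: str = "chr",
    build_preference: Tuple[str, ...] = ("GRCh37", "GRCh38"),
) -> Tuple[List[VariantRecord], ReadReport]:
    """Read a COSMIC Cancer Mutation Census TSV, keeping tier 1-3 mutations.

    The genomic position is taken from the first available
    ``Mutation genome position <build>`` column in *build_preference*.
    Rows with zero tested samples or unparseable coordinates are dropped
    and counted in the skip report.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    gene_col = _require(df, "GENE_NAME")
    tier_col = _require(df, "MUTATION_SIGNIFICANCE_TIER")
    pos_col = None
    for build in build_preference:
        try:
            pos_col = _require(df, f"Mutation genome position {build}")
            break
        except VariantTableError:
            continue
    if pos_col is None:
        raise VariantTableError(
            "no 'Mutation genome position <build>' column for any of "
            f"{build_preference}"
        )
    mutated_col = _require(df, "COSMIC_SAMPLE_MUTATED")
    tested_col = _require(df, "COSMIC_SAMPLE_TESTED")
    id_col = next(
        (c for c in df.columns if c.upper() in ("GENOMIC_MUTATION_ID", "MUTATION_ID")),
        gene_col,
    )
    aa_col = next((c for c in df.columns if c.upper() == "MUTATION_AA"), None)

    report = ReadReport(total_rows=len(df))
    records: List[VariantRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        d = dict(zip(df.columns, row))
        tier = str(d[tier_col]).strip()
        if tier not in _CMC_TIERS:
            report.dropped_filter += 1
            continue
        m = _POSITION_RE.match(str(d[pos_col]).strip())
        if not m:
            report.skip("unparseable genome position")
            continue
        try:
            mutated = int(d[mutated_col])
            tested = int(d[tested_col])
        except ValueError:
            report.skip("non-integer sample counts")
            continue
        if tested <= 0:
            report.skip("zero tested samples")
            continue
        start, end = int(m.group(2)), int(m.group(3))
        records.append(
            VariantRecord(
                source=COSMIC,
                record_id=str(d[id_col]) or f"row{i}",
                gene_symbol=str(d[gene_col]),
                chrom=normalize_chrom(m.group(1), chrom_style),
                start=start,
                end=end,
                classification=f"Tier {tier}",
                positive_samples=mutated,
                tested_samples=tested,
                hgvs_label=str(d[aa_col]) if aa_col else "",
            )
        )
    report.retained = len(records)
    return records, report
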