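"""BED target/mask file handling and the PanelDefinition container.

BED records are 0-based half-open; they are converted to the package's
1-based closed convention on read (``start + 1, end``) and back on write.
Only the first three columns are used; ``track``, ``browser`` and ``#``
lines are skipped and counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .intervals import GenomicInterval, IntervalSet, normalize_chrom

log = logging.getLogger(__name__)


class BedParseError(ValueError):
    """A BED line could not be parsed; the message carries file and line number."""


@dataclass
class BedResult:
    intervals: List[GenomicInterval]
    data_lines: int
    comment_lines: int
    path: str


def read_bed(path: str, chrom_style: str = "chr") -> BedResult:
    """Parse a BED file into 1-based closed intervals.

    Raises :class:`BedParseError` on non-integer coordinates, ``end <=
    start`` (in BED's half-open terms, an empty or negative feature), or a
    file with zero data lines.
    """
    intervals: List[GenomicInterval] = []
    comments = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(("#", "track", "browser")):
                comments += 1
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}"
                )
            chrom = normalize_chrom(fields[0], chrom_style)
            try:
                start0, end0 = int(fields[1]), int(fields[2])
            except ValueError:
                raise BedParseError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}, {fields[2]!r}"
                ) from None
            if end0 <= start0 or start0 < 0:
                raise BedParseError(
                    f"{path}:{lineno}: invalid BED span [{start0}, {end0})"
                )
            intervals.append(GenomicInterval(chrom, start0 + 1, end0))
    if not intervals:
        raise BedParseError(f"{path}: no data lines")
    return BedResult(
        intervals=intervals, data_lines=len(intervals), comment_lines=comments, path=path
    )


def write_bed(s: IntervalSet, path: str) -> None:
    """Write a normalized IntervalSet as minimal 3-column BED (the inverse of read_bed)."""
    with open(path, "w") as fh:
        for iv in s:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\n")


@dataclass
class PanelDefinition:
    """A named panel: merged target regions plus an optional variant mask."""

    name: str
    target: IntervalSet
    mask: IntervalSet = field(default_factory=IntervalSet)
    source_files: Tuple[str, ...] = ()
    record_count: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("panel name must be non-empty")
        if not self.target:
            raise ValueError(f"panel {self.name!r}: empty target set")

    @property
    def masked_target(self) -> IntervalSet:
        return self.target.intersect(self.mask)


def load_panel(
    name: str,
    target_path: str,
    mask_path: Optional[str] = None,
    chrom_style: str = "chr",
) -> PanelDefinition:
    """Read target (and optional mask) BED files into a PanelDefinition."""
    tgt = read_bed(target_path, chrom_style)
    sources = [target_path]
    mask = IntervalSet()
    if mask_path is not None:
        msk = read_bed(mask_path, chrom_style)
        mask = IntervalSet(msk.intervals)
        sources.append(mask_path)
    panel = PanelDefinition(
        name=name,
        target=IntervalSet(tgt.intervals),
        mask=mask,
        source_files=tuple(sources),
        record_count=tgt.data_lines,
    )
    log.info(
        "panel %s: %d target records -> %d merged intervals (%d bases), mask %d bases",
        name,
        tgt.data_lines,
        len(panel.target),
        panel.target.total_length,
        panel.mask.total_length,
    )
    return panel
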