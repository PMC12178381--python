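"""Exact interval-set algebra on 1-based closed genomic coordinates.

Every coverage and variant-classification computation in this package is
set arithmetic over genomic base positions.  The substrate is a normalized
:class:`IntervalSet`: per chromosome, a sorted list of non-overlapping,
non-adjacent closed intervals.  Two intervals that touch (``end + 1 ==
next.start``) cover contiguous bases and are merged during normalization,
so an IntervalSet is a canonical representation of a set of bases and two
IntervalSets compare equal iff they cover the same bases.

Coordinates are 1-based closed throughout (the GenomicRanges convention);
conversion from BED's 0-based half-open form happens at the I/O boundary
only.  Strand is deliberately not modeled: panel coverage is per-base and
strandless.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple


class IntervalError(ValueError):
    """An interval violates the coordinate invariants (start >= 1, start <= end)."""


def normalize_chrom(name: str, style: str = "chr") -> str:
    """Return *name* in the requested chromosome-naming style.

    ``style="chr"`` yields UCSC-style names (``chr1``), ``style="plain"``
    yields bare names (``1``).  Mixed input styles (panel BED vs. annotation)
    are thereby reconciled automatically.
    """
    if not name:
        raise IntervalError("empty chromosome name")
    bare = name[3:] if name.lower().startswith("chr") else name
    if not bare:
        raise IntervalError(f"chromosome name {name!r} is only a prefix")
    if style == "chr":
        return "chr" + bare
    if style == "plain":
        return bare
    raise ValueError(f"unknown chromosome style {style!r}")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed 1-based interval ``[start, end]`` on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError("interval with empty chromosome name")
        if self.start < 1:
            raise IntervalError(
                f"interval {self.chrom}:{self.start}-{self.end}: start < 1 "
                "(coordinates are 1-based)"
            )
        if self.end < self.start:
            raise IntervalError(
                f"interval {self.chrom}:{self.start}-{self.end}: end < start"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:  # pragma: no cover - display only
        return f"{self.chrom}:{self.start}-{self.end}"


_Chrom = Dict[str, List[Tuple[int, int]]]


class IntervalSet:
    """A normalized set of genomic bases, stored as merged intervals per chromosome."""

    __slots__ = ("_by_chrom",)

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self._by_chrom: _Chrom = _merge(intervals)

    # -- construction -------------------------------------------------

    @classmethod
    def from_tuples(cls, tuples: Iterable[Tuple[str, int, int]]) -> "IntervalSet":
        return cls(GenomicInterval(c, s, e) for c, s, e in tuples)

    @classmethod
    def _from_normalized(cls, by_chrom: _Chrom) -> "IntervalSet":
        obj = cls.__new__(cls)
        obj._by_chrom = {c: ivs for c, ivs in sorted(by_chrom.items()) if ivs}
        return obj

    # -- basic protocol -----------------------------------------------

    def __iter__(self) -> Iterator[GenomicInterval]:
        for chrom in self._by_chrom:
            for s, e in self._by_chrom[chrom]:
                yield GenomicInterval(chrom, s, e)

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_chrom.values())

    def __bool__(self) -> bool:
        return bool(self._by_chrom)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self._by_chrom == other._by_chrom

    def __hash__(self) -> int:
        return hash(tuple((c, tuple(v)) for c, v in self._by_chrom.items()))

    def __repr__(self) -> str:  # pragma: no cover - display only
        n = len(self)
        return f"<IntervalSet {n} interval{'s' if n != 1 else ''}, {self.total_length} bases>"

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(self._by_chrom)

    @property
    def total_length(self) -> int:
        """Number of distinct bases covered."""
        return sum(e - s + 1 for ivs in self._by_chrom.values() for s, e in ivs)

    # -- set algebra ---------------------------------------------------

    def union(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet(list(self) + list(other))

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out: _Chrom = {}
        for chrom in self._by_chrom:
            b = other._by_chrom.get(chrom)
            if b:
                merged = _intersect_sorted(self._by_chrom[chrom], b)
                if merged:
                    out[chrom] = merged
        return IntervalSet._from_normalized(out)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out: _Chrom = {}
        for chrom, a in self._by_chrom.items():
            b = other._by_chrom.get(chrom)
            res = _subtract_sorted(a, b) if b else list(a)
            if res:
                out[chrom] = res
        return IntervalSet._from_normalized(out)

    # -- queries --------------------------------------------------------

    def overlaps(self, iv: GenomicInterval) -> bool:
        """True iff at least one base of *iv* lies in this set."""
        ivs = self._by_chrom.get(iv.chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (iv.end, float("inf"))) - 1
        return i >= 0 and ivs[i][1] >= iv.start

    def contains(self, iv: GenomicInterval) -> bool:
        """True iff every base of *iv* lies in this set.

        On a normalized set a fully contained span must sit inside a single
        merged interval.
        """
        ivs = self._by_chrom.get(iv.chrom)
        if not ivs:
            return False
        i = bisect_right(ivs, (iv.start, float("inf"))) - 1
        return i >= 0 and ivs[i][0] <= iv.start and iv.end <= ivs[i][1]

    def with_chrom_style(self, style: str) -> "IntervalSet":
        return IntervalSet(
            GenomicInterval(normalize_chrom(iv.chrom, style), iv.start, iv.end)
            for iv in self
        )


def _merge(intervals: Iterable[GenomicInterval]) -> _Chrom:
    grouped: Dict[str, List[Tuple[int, int]]] = {}
    for iv in intervals:
        grouped.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out: _Chrom = {}
    for chrom in sorted(grouped):
        pairs = sorted(grouped[chrom])
        merged: List[Tuple[int, int]] = []
        cur_s, cur_e = pairs[0]
        for s, e in pairs[1:]:
            if s <= cur_e + 1:  # overlap or adjacency: same base run
                cur_e = max(cur_e, e)
            else:
                merged.append((cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((cur_s, cur_e))
        out[chrom] = merged
    return out


def _intersect_sorted(
    a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s <= e:
            out.append((s, e))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def _subtract_sorted(
    a: Sequence[Tuple[int, int]], b: Sequence[Tuple[int, int]]
) -> List[Tuple[int, int]]:
    out: List[Tuple[int, int]] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] < cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] <= e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs - 1))
            cur = max(cur, be + 1)
            if cur > e:
                break
            k += 1
        if cur <= e:
            out.append((cur, e))
    return out


def normalize(intervals: Iterable[GenomicInterval]) -> IntervalSet:
    """Canonical merged form of a collection of intervals.

    Idempotent and insensitive to input order; overlapping and adjacent
    intervals are merged into maximal base runs.
    """
    return IntervalSet(intervals)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.intersect(b)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.subtract(b)


def union(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.union(b)


def total_length(s: IntervalSet) -> int:
    return s.total_length


def overlaps_any(iv: GenomicInterval, s: IntervalSet) -> bool:
    return s.overlaps(iv)
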