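"""Interval algebra: closed-coordinate semantics and base-set equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from panelaudit.intervals import (
    GenomicInterval,
    IntervalError,
    IntervalSet,
    normalize,
    normalize_chrom,
)

from conftest import base_set


def ivs(*tuples):
    return IntervalSet.from_tuples(tuples)


def as_tuples(s):
    return [(iv.chrom, iv.start, iv.end) for iv in s]


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [
            # overlap merge
            ([("chr1", 1, 10), ("chr1", 5, 20)], [("chr1", 1, 20)]),
            # adjacency merge: 1-10 and 11-20 cover contiguous bases
            ([("chr1", 1, 10), ("chr1", 11, 20)], [("chr1", 1, 20)]),
            # gap of one base stays split
            ([("chr1", 1, 10), ("chr1", 12, 20)], [("chr1", 1, 10), ("chr1", 12, 20)]),
            # chromosomes kept apart
            ([("chr2", 1, 5), ("chr1", 1, 5)], [("chr1", 1, 5), ("chr2", 1, 5)]),
        ],
    )
    def test_merge_semantics(self, raw, expected):
        assert as_tuples(ivs(*raw)) == expected

    def test_invalid_intervals_are_named(self):
        with pytest.raises(IntervalError, match="chr1:10-5"):
            GenomicInterval("chr1", 10, 5)
        with pytest.raises(IntervalError, match="start < 1"):
            GenomicInterval("chr1", 0, 5)
        with pytest.raises(IntervalError):
            GenomicInterval("", 1, 5)

    def test_idempotent_and_order_invariant(self):
        raw = [("chr1", 5, 9), ("chr1", 1, 6), ("chr2", 3, 3), ("chr1", 10, 12)]
        a = ivs(*raw)
        b = ivs(*reversed(raw))
        assert a == b
        assert IntervalSet(list(a)) == a


class TestAlgebraExamples:
    def test_intersect(self):
        assert as_tuples(ivs(("chr1", 1, 10)).intersect(ivs(("chr1", 5, 20)))) == [
            ("chr1", 5, 10)
        ]

    def test_intersect_chrom_mismatch_is_empty(self):
        assert not ivs(("chr1", 1, 10)).intersect(ivs(("chr2", 1, 10)))

    def test_subtract_middle_cut(self):
        assert as_tuples(ivs(("chr1", 1, 20)).subtract(ivs(("chr1", 5, 10)))) == [
            ("chr1", 1, 4),
            ("chr1", 11, 20),
        ]

    def test_self_subtraction_empty(self):
        a = ivs(("chr1", 1, 20), ("chr2", 5, 9))
        assert not a.subtract(a)
        assert a.subtract(IntervalSet()) == a

    def test_total_length_closed_convention(self):
        assert ivs(("chr1", 1, 10)).total_length == 10
        assert ivs(("chr1", 1, 10), ("chr2", 1, 5)).total_length == 15
        assert IntervalSet().total_length == 0

    def test_overlaps_boundary_base(self):
        s = ivs(("chr1", 1, 10))
        assert s.overlaps(GenomicInterval("chr1", 10, 10))
        assert not s.overlaps(GenomicInterval("chr1", 11, 12))
        assert not s.overlaps(GenomicInterval("chr2", 5, 5))

    def test_contains_requires_full_span(self):
        s = ivs(("chr1", 5, 10))
        assert s.contains(GenomicInterval("chr1", 5, 10))
        assert not s.contains(GenomicInterval("chr1", 4, 10))
        assert not s.contains(GenomicInterval("chr1", 8, 11))


def random_interval_list(rng, n_max=30, chrom_len=10_000, chroms=("chr1", "chr2")):
    n = rng.integers(1, n_max + 1)
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(0, len(chroms))]
        s = int(rng.integers(1, chrom_len))
        e = min(chrom_len, s + int(rng.integers(0, 200)))
        out.append(GenomicInterval(chrom, s, e))
    return out


class TestBaseSetOracle:
    """Exact agreement with per-base set arithmetic on a 10 kb toy chromosome."""

    def test_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            raw_a = random_interval_list(rng)
            raw_b = random_interval_list(rng)
            a, b = IntervalSet(raw_a), IntervalSet(raw_b)
            sa, sb = base_set(raw_a), base_set(raw_b)
            assert base_set(a) == sa  # normalize preserves the base set
            assert a.total_length == len(sa)
            assert base_set(a.intersect(b)) == (sa & sb)
            assert base_set(a.subtract(b)) == (sa - sb)
            assert base_set(a.union(b)) == (sa | sb)

    def test_point_membership_queries(self):
        rng = np.random.default_rng(7)
        raw = random_interval_list(rng, n_max=50)
        s = IntervalSet(raw)
        bases = base_set(raw)
        for _ in range(1000):
            chrom = ("chr1", "chr2")[rng.integers(0, 2)]
            p = int(rng.integers(1, 10_001))
            assert s.overlaps(GenomicInterval(chrom, p, p)) == ((chrom, p) in bases)


@st.composite
def interval_sets(draw):
    n = draw(st.integers(1, 12))
    out = []
    for _ in range(n):
        s = draw(st.integers(1, 500))
        out.append(GenomicInterval("chr1", s, s + draw(st.integers(0, 60))))
    return IntervalSet(out)


@settings(max_examples=100, derandomize=True)
@given(interval_sets(), interval_sets())
def test_length_identity(a, b):
    """|A| + |B| = |A u B| + |A n B| on normalized sets."""
    assert a.total_length + b.total_length == (
        a.union(b).total_length + a.intersect(b).total_length
    )


@settings(max_examples=100, derandomize=True)
@given(interval_sets(), interval_sets())
def test_partition_consistency(a, b):
    """A n B equals A - (A - B)."""
    assert a.intersect(b) == a.subtract(a.subtract(b))


@settings(max_examples=100, derandomize=True)
@given(interval_sets(), interval_sets())
def test_intersect_commutes_and_is_subset(a, b):
    inter = a.intersect(b)
    assert inter == b.intersect(a)
    assert inter.subtract(a).total_length == 0
    assert inter.subtract(b).total_length == 0


@pytest.mark.parametrize(
    "name, style, expected",
    [
        ("1", "chr", "chr1"),
        ("chr1", "chr", "chr1"),
        ("chrX", "plain", "X"),
        ("MT", "chr", "chrMT"),
    ],
)
def test_chrom_style_normalization(name, style, expected):
    assert normalize_chrom(name, style) == expected
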