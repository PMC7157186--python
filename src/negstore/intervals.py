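"""Half-open genomic interval arithmetic on sorted, merged interval lists.

All coordinates are 0-based, half-open ``[start, end)``.  Every public
function both accepts and returns *canonical* interval lists: sorted by
start, pairwise disjoint and non-adjacent (maximally merged).  The
:class:`TargetRegionSet` container holds one canonical list per chromosome
and is the package-wide representation of a capture kit's target regions
and of the cohort region of interest.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Sequence, Tuple

Interval = Tuple[int, int]


def merge_intervals(intervals: Iterable[Interval]) -> List[Interval]:
    """Sort and maximally merge intervals (touching intervals coalesce)."""
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    out: List[Interval] = []
    for s, e in ivs:
        if s >= e:
            raise ValueError(f"empty or inverted interval [{s}, {e})")
        if out and s <= out[-1][1]:
            if e > out[-1][1]:
                out[-1] = (out[-1][0], e)
        else:
            out.append((s, e))
    return out


def total_length(intervals: Sequence[Interval]) -> int:
    return sum(e - s for s, e in intervals)


def contains(intervals: Sequence[Interval], pos: int) -> bool:
    """Membership test on a canonical list via binary search."""
    i = bisect_right(intervals, (pos, float("inf"))) - 1
    return i >= 0 and intervals[i][0] <= pos < intervals[i][1]


def clip(intervals: Sequence[Interval], start: int, end: int) -> List[Interval]:
    """Intersection of a canonical list with a single window [start, end)."""
    if start >= end:
        return []
    out = []
    i = max(bisect_right(intervals, (start, float("inf"))) - 1, 0)
    for s, e in intervals[i:]:
        if s >= end:
            break
        lo, hi = max(s, start), min(e, end)
        if lo < hi:
            out.append((lo, hi))
    return out


def intersect(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Intersection of two canonical lists (linear sweep)."""
    out: List[Interval] = []
    i = j = 0
    while i < len(a) and j < len(b):
        lo = max(a[i][0], b[j][0])
        hi = min(a[i][1], b[j][1])
        if lo < hi:
            out.append((lo, hi))
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return out


def subtract(a: Sequence[Interval], b: Sequence[Interval]) -> List[Interval]:
    """Set difference a \\ b of two canonical lists."""
    out: List[Interval] = []
    j = 0
    for s, e in a:
        cur = s
        while j < len(b) and b[j][1] <= cur:
            j += 1
        k = j
        while k < len(b) and b[k][0] < e:
            bs, be = b[k]
            if bs > cur:
                out.append((cur, bs))
            cur = max(cur, be)
            if be >= e:
                break
            k += 1
        if cur < e:
            out.append((cur, e))
    return out


def positions_to_intervals(positions: Sequence[int]) -> List[Interval]:
    """Collapse a sorted list of distinct positions into maximal runs."""
    out: List[Interval] = []
    for p in positions:
        if out and p == out[-1][1]:
            out[-1] = (out[-1][0], p + 1)
        else:
            out.append((p, p + 1))
    return out


@dataclass
class TargetRegionSet:
    """A named set of tested genomic intervals (capture-kit targets or ROI).

    ``intervals`` maps chromosome name to a canonical interval list.  The
    constructor canonicalises whatever it is given, so invariants (sorted,
    disjoint, maximally merged, start < end) hold for every instance.
    """

    kit_id: str
    intervals: Dict[str, List[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = {
            chrom: merge_intervals(ivs) for chrom, ivs in self.intervals.items() if ivs
        }

    @classmethod
    def from_records(cls, kit_id: str, records: Iterable[Tuple[str, int, int]]) -> "TargetRegionSet":
        by_chrom: Dict[str, List[Interval]] = {}
        for chrom, s, e in records:
            by_chrom.setdefault(chrom, []).append((s, e))
        return cls(kit_id, by_chrom)

    def contains(self, chrom: str, pos: int) -> bool:
        ivs = self.intervals.get(chrom)
        return bool(ivs) and contains(ivs, pos)

    def covers_interval(self, chrom: str, start: int, end: int) -> bool:
        """True iff every base of [start, end) is targeted."""
        clipped = clip(self.intervals.get(chrom, []), start, end)
        return total_length(clipped) == end - start

    def clip(self, chrom: str, start: int, end: int) -> List[Interval]:
        return clip(self.intervals.get(chrom, []), start, end)

    @property
    def total_bases(self) -> int:
        return sum(total_length(ivs) for ivs in self.intervals.values())

    def iter_records(self) -> Iterator[Tuple[str, int, int]]:
        for chrom in self.intervals:
            for s, e in self.intervals[chrom]:
                yield chrom, s, e

    def padded(self, pad_bp: int, chrom_lengths: Dict[str, int] | None = None) -> "TargetRegionSet":
        """Symmetric padding, clamped at 0 and (if known) the chromosome end."""
        if pad_bp < 0:
            raise ValueError("pad_bp must be >= 0")
        recs = []
        for chrom, s, e in self.iter_records():
            lo = max(0, s - pad_bp)
            hi = e + pad_bp
            if chrom_lengths and chrom in chrom_lengths:
                hi = min(hi, chrom_lengths[chrom])
            recs.append((chrom, lo, hi))
        return TargetRegionSet.from_records(self.kit_id, recs)

    def union(self, other: "TargetRegionSet", kit_id: str = "union") -> "TargetRegionSet":
        recs = list(self.iter_records()) + list(other.iter_records())
        return TargetRegionSet.from_records(kit_id, recs)

    def __bool__(self) -> bool:
        return any(self.intervals.values())
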