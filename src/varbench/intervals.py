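"""Interval-set algebra over half-open genomic regions.

A :class:`RegionSet` is the normalized form used by all region arithmetic:
per chromosome a sorted list of non-overlapping, non-abutting intervals.
Semantics are those of sets of integer base positions, so abutting intervals
merge and ``|A| = |A∩B| + |A\\B|`` holds exactly.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np

from .core_io import Region
from .errors import DomainError

__all__ = [
    "RegionSet",
    "normalize",
    "intersect",
    "subtract",
    "union",
    "covered_fraction",
    "contains",
    "edge_distance",
]


class RegionSet:
    """Sorted, merged, non-overlapping intervals per chromosome."""

    __slots__ = ("_data",)

    def __init__(self, _data: dict[str, tuple[np.ndarray, np.ndarray]] | None = None):
        # invariant: starts strictly increasing, ends[i] < starts[i+1]
        self._data = _data or {}

    # -- construction --------------------------------------------------

    @classmethod
    def from_regions(cls, regions: Iterable[Region]) -> "RegionSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
        data = {}
        for chrom in sorted(by_chrom):
            ivs = sorted(by_chrom[chrom])
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:  # overlap or abut
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            data[chrom] = (
                np.array([m[0] for m in merged], dtype=np.int64),
                np.array([m[1] for m in merged], dtype=np.int64),
            )
        return cls(data)

    # -- basic queries --------------------------------------------------

    @property
    def chroms(self) -> list[str]:
        return sorted(self._data)

    def regions(self) -> list[Region]:
        out = []
        for chrom in self.chroms:
            starts, ends = self._data[chrom]
            out.extend(Region(chrom, int(s), int(e)) for s, e in zip(starts, ends))
        return out

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions())

    def __len__(self) -> int:
        return sum(len(s) for s, _ in self._data.values())

    def __bool__(self) -> bool:
        return any(len(s) for s, _ in self._data.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegionSet):
            return NotImplemented
        if set(self._data) != set(other._data):
            # empty chromosomes are equivalent to absent ones
            a = {c for c in self._data if len(self._data[c][0])}
            b = {c for c in other._data if len(other._data[c][0])}
            if a != b:
                return False
        for chrom in self._data:
            if chrom not in other._data:
                if len(self._data[chrom][0]):
                    return False
                continue
            s1, e1 = self._data[chrom]
            s2, e2 = other._data[chrom]
            if not (np.array_equal(s1, s2) and np.array_equal(e1, e2)):
                return False
        return True

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} intervals, {self.total_length} bases)"

    @property
    def total_length(self) -> int:
        return int(sum((e - s).sum() for s, e in self._data.values()))

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position."""
        return self._locate(chrom, pos - 1) is not None

    def edge_distance(self, chrom: str, pos: int) -> int | None:
        """Distance (in bases) from a 1-based position to the nearest boundary
        of its enclosing interval; the first/last base of an interval has
        distance 0.  ``None`` when the position is outside the set."""
        hit = self._locate(chrom, pos - 1)
        if hit is None:
            return None
        s, e = hit
        pos0 = pos - 1
        return int(min(pos0 - s, e - 1 - pos0))

    def _locate(self, chrom: str, pos0: int) -> tuple[int, int] | None:
        if chrom not in self._data:
            return None
        starts, ends = self._data[chrom]
        i = int(np.searchsorted(starts, pos0, side="right")) - 1
        if i >= 0 and pos0 < ends[i]:
            return int(starts[i]), int(ends[i])
        return None

    # -- algebra ---------------------------------------------------------

    def union(self, other: "RegionSet") -> "RegionSet":
        return RegionSet.from_regions(list(self) + list(other))

    def intersect(self, other: "RegionSet") -> "RegionSet":
        data = {}
        for chrom in self._data:
            if chrom not in other._data:
                continue
            s1, e1 = self._data[chrom]
            s2, e2 = other._data[chrom]
            out_s, out_e = [], []
            i = j = 0
            while i < len(s1) and j < len(s2):
                lo = max(s1[i], s2[j])
                hi = min(e1[i], e2[j])
                if lo < hi:
                    out_s.append(lo)
                    out_e.append(hi)
                if e1[i] <= e2[j]:
                    i += 1
                else:
                    j += 1
            if out_s:
                data[chrom] = (
                    np.array(out_s, dtype=np.int64),
                    np.array(out_e, dtype=np.int64),
                )
        return RegionSet(data)

    def subtract(self, other: "RegionSet") -> "RegionSet":
        data = {}
        for chrom in self._data:
            s1, e1 = self._data[chrom]
            if chrom not in other._data:
                if len(s1):
                    data[chrom] = (s1.copy(), e1.copy())
                continue
            s2, e2 = other._data[chrom]
            out_s, out_e = [], []
            j = 0
            for s, e in zip(s1, e1):
                cur = int(s)
                while j < len(s2) and e2[j] <= cur:
                    j += 1
                k = j
                while k < len(s2) and s2[k] < e:
                    if s2[k] > cur:
                        out_s.append(cur)
                        out_e.append(int(s2[k]))
                    cur = max(cur, int(e2[k]))
                    if e2[k] >= e:
                        break
                    k += 1
                if cur < e:
                    out_s.append(cur)
                    out_e.append(int(e))
            if out_s:
                data[chrom] = (
                    np.array(out_s, dtype=np.int64),
                    np.array(out_e, dtype=np.int64),
                )
        return RegionSet(data)

    def covered_fraction(self, cover: "RegionSet") -> float:
        """Fraction of this set's bases that fall inside ``cover``."""
        total = self.total_length
        if total == 0:
            raise DomainError("covered_fraction of an empty target is undefined")
        return self.intersect(cover).total_length / total


# ---------------------------------------------------------------------------
# Functional aliases matching the operation-style API.


def normalize(regions: Iterable[Region]) -> RegionSet:
    return RegionSet.from_regions(regions)


def intersect(a: RegionSet, b: RegionSet) -> RegionSet:
    return a.intersect(b)


def subtract(a: RegionSet, b: RegionSet) -> RegionSet:
    return a.subtract(b)


def union(a: RegionSet, b: RegionSet) -> RegionSet:
    return a.union(b)


def covered_fraction(target: RegionSet, cover: RegionSet) -> float:
    return target.covered_fraction(cover)


def contains(regionset: RegionSet, chrom: str, pos: int) -> bool:
    return regionset.contains(chrom, pos)


def edge_distance(regionset: RegionSet, chrom: str, pos: int) -> int | None:
    return regionset.edge_distance(chrom, pos)
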