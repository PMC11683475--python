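"""Genomic interval primitives and the interval algebra used across the package.

All intervals are BED-convention: 0-based, half-open ``[start, end)``. Every
consumer of interval sets in this package (state segmentations, peak sets,
TADs, sweep regions) goes through the functions here, so the half-open
convention is enforced in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "merge_intervals",
    "total_bp",
    "overlap_bp",
    "points_in_intervals",
    "count_overlaps",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval with optional BED6 annotations."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}")
        if self.strand is not None and self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


class IntervalSet:
    """Per-chromosome sorted interval arrays; the workhorse container.

    Internally stores, per chromosome, two int arrays (starts, ends) sorted by
    start. Construction sorts; ``merged()`` additionally collapses overlapping
    or book-ended intervals.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        chroms: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            chroms.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in chroms.items():
            self._by_chrom[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self._by_chrom:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty
        return self._by_chrom[chrom]

    def merged(self) -> "IntervalSet":
        return IntervalSet(merge_intervals(self.intervals))

    def total_bp(self) -> int:
        return total_bp(self.intervals)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Collapse overlapping or book-ended intervals (bedtools-merge semantics)."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end, name=prev.name)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name))
    return out


def total_bp(intervals: Iterable[GenomicInterval]) -> int:
    """Base pairs covered by the union of `intervals`."""
    return sum(iv.length for iv in merge_intervals(intervals))


def overlap_bp(a: IntervalSet | Sequence[GenomicInterval],
               b: IntervalSet | Sequence[GenomicInterval]) -> int:
    """Base pairs in the intersection of the unions of two interval sets."""
    a = a if isinstance(a, IntervalSet) else IntervalSet(a)
    b = b if isinstance(b, IntervalSet) else IntervalSet(b)
    am, bm = a.merged(), b.merged()
    bp = 0
    for chrom in am.chroms:
        s1, e1 = am.arrays(chrom)
        s2, e2 = bm.arrays(chrom)
        if len(s2) == 0 or len(s1) == 0:
            continue
        i = j = 0
        while i < len(s1) and j < len(s2):
            lo = max(s1[i], s2[j])
            hi = min(e1[i], e2[j])
            if hi > lo:
                bp += int(hi - lo)
            if e1[i] <= e2[j]:
                i += 1
            else:
                j += 1
    return bp


def points_in_intervals(chroms: Sequence[str], positions: Sequence[int],
                        ivset: IntervalSet) -> np.ndarray:
    """Boolean membership of 0-based point positions in a *merged* interval set.

    A point equal to an interval end is outside (half-open convention).
    """
    m = ivset.merged()
    positions = np.asarray(positions, dtype=np.int64)
    out = np.zeros(len(positions), dtype=bool)
    chroms_arr = np.asarray(chroms, dtype=object)
    for chrom in m.chroms:
        mask = chroms_arr == chrom
        if not mask.any():
            continue
        starts, ends = m.arrays(chrom)
        pos = positions[mask]
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, None)])
        out[mask] = ok
    return out


def count_overlaps(query: Sequence[GenomicInterval], subject: IntervalSet) -> np.ndarray:
    """Number of subject intervals overlapping (>= 1 bp) each query interval."""
    counts = np.zeros(len(query), dtype=np.int64)
    for qi, iv in enumerate(query):
        starts, ends = subject.arrays(iv.chrom)
        if len(starts) == 0:
            continue
        counts[qi] = int(np.sum((starts < iv.end) & (ends > iv.start)))
    return counts
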