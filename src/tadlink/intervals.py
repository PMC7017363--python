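"""Genomic interval primitives.

All coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Chromosome names are compared as exact strings; no
``chr``-prefix normalization happens here (the I/O layer offers it as an
option).  Intervals are unstranded — TADs and DMRs have no orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "interval_length",
    "overlap_length",
    "jaccard",
]


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome.

    Invariants: ``start >= 0`` and ``end > start`` (zero-length intervals
    are rejected; every interval spans at least one base).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self!r}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval: {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def interval_length(iv: GenomicInterval) -> int:
    """Length of ``iv`` in base pairs (``end - start``)."""
    return iv.end - iv.start


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by ``a`` and ``b`` (0 on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    """Jaccard overlap: intersection length over union length.

    The union is the set union of covered bases, i.e. ``len(a) + len(b) -
    overlap``; for disjoint same-chromosome intervals the gap between them
    is *not* part of the union (the value is then simply 0 because the
    intersection is empty).
    """
    inter = overlap_length(a, b)
    if inter == 0 and a.chrom != b.chrom:
        return 0.0
    union = a.length + b.length - inter
    return inter / union


class _ChromIndex:
    """Per-chromosome coordinate arrays sorted by (start, end).

    ``starts``/``ends`` are int64 arrays; ``order`` maps sorted position
    back to the index in the owning :class:`IntervalSet`.  ``end_prefix_max``
    supports O(log m) any-overlap queries on possibly overlapping intervals.
    """

    __slots__ = ("starts", "ends", "order", "end_prefix_max")

    def __init__(self, starts: np.ndarray, ends: np.ndarray, order: np.ndarray):
        self.starts = starts
        self.ends = ends
        self.order = order
        self.end_prefix_max = np.maximum.accumulate(ends)


class IntervalSet:
    """An ordered collection of intervals with a track label and ids.

    Input order is preserved for deterministic iteration; chromosome-level
    numpy indexes are built lazily for vectorized queries.
    """

    def __init__(
        self,
        intervals: Iterable[GenomicInterval],
        label: str = "",
        ids: Sequence[str] | None = None,
    ):
        self.intervals: list[GenomicInterval] = list(intervals)
        self.label = label
        if ids is None:
            ids = [f"{label or 'iv'}_{i:05d}" for i in range(len(self.intervals))]
        else:
            ids = list(ids)
            if len(ids) != len(self.intervals):
                raise ValueError("ids and intervals length mismatch")
        self.ids: list[str] = ids
        self._index: dict[str, _ChromIndex] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def _build(self) -> dict[str, _ChromIndex]:
        if self._index is None:
            groups: dict[str, list[int]] = {}
            for i, iv in enumerate(self.intervals):
                groups.setdefault(iv.chrom, []).append(i)
            index = {}
            for chrom, idx in groups.items():
                idx_arr = np.asarray(idx, dtype=np.int64)
                starts = np.asarray([self.intervals[i].start for i in idx], dtype=np.int64)
                ends = np.asarray([self.intervals[i].end for i in idx], dtype=np.int64)
                order = np.lexsort((ends, starts))
                index[chrom] = _ChromIndex(starts[order], ends[order], idx_arr[order])
            self._index = index
        return self._index

    def chrom_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, original_index) for ``chrom``, sorted by start."""
        index = self._build()
        if chrom not in index:
            empty = np.empty(0, dtype=np.int64)
            return empty, empty, empty
        ci = index[chrom]
        return ci.starts, ci.ends, ci.order

    def overlaps_any(self, chrom: str, qstarts: np.ndarray, qends: np.ndarray) -> np.ndarray:
        """Boolean array: does each query interval overlap any member interval?"""
        qstarts = np.asarray(qstarts, dtype=np.int64)
        qends = np.asarray(qends, dtype=np.int64)
        index = self._build()
        if chrom not in index:
            return np.zeros(qstarts.shape, dtype=bool)
        ci = index[chrom]
        # members with start < qend are candidates; overlap iff one of them
        # has end > qstart, i.e. the running max end among them exceeds qstart
        k = np.searchsorted(ci.starts, qends, side="left")
        out = np.zeros(qstarts.shape, dtype=bool)
        nz = k > 0
        out[nz] = ci.end_prefix_max[k[nz] - 1] > qstarts[nz]
        return out

    def total_span(self) -> int:
        """Total bases covered (overlaps between members counted once)."""
        total = 0
        for chrom in self.chroms():
            starts, ends, _ = self.chrom_arrays(chrom)
            cur_s, cur_e = None, None
            for s, e in zip(starts.tolist(), ends.tolist()):
                if cur_e is None or s > cur_e:
                    if cur_e is not None:
                        total += cur_e - cur_s
                    cur_s, cur_e = s, e
                else:
                    cur_e = max(cur_e, e)
            if cur_e is not None:
                total += cur_e - cur_s
        return total
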