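"""Genomic interval primitives.

All coordinates are 0-based, half-open ``[start, end)``, the BED convention.
Two overlap notions are used in the package and kept explicit throughout:

* *merging* treats book-ended intervals (``a.end == b.start``) as joinable;
* *annotation* (state flags, presence calls) requires >= 1 bp of true
  intersection, so book-ended intervals do NOT overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

__all__ = [
    "GenomicInterval",
    "merge_intervals",
    "overlaps_any",
    "overlap_length",
    "pair_by_max_overlap",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval with optional BED6+1 annotations.

    ``score`` carries the per-peak tag density where applicable; ``sample``
    is the extra seventh column used for per-sample peak files.
    """

    chrom: str
    start: int
    end: int
    name: str = ""
    score: float = 0.0
    strand: str = "."
    sample: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"unknown strand character {self.strand!r}")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", book_ended: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if book_ended:
            return self.start <= other.end and other.start <= self.end
        return self.start < other.end and other.start < self.end


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(
    intervals: Iterable[GenomicInterval], book_ended: bool = True
) -> list[GenomicInterval]:
    """Union-merge intervals into disjoint loci.

    With ``book_ended=True`` (default, used for master-peak construction)
    intervals touching end-to-start are merged into one locus.
    """
    ivs = sorted(intervals, key=lambda r: (r.chrom, r.start, r.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged:
            last = merged[-1]
            joinable = last.chrom == iv.chrom and (
                iv.start <= last.end if book_ended else iv.start < last.end
            )
            if joinable:
                if iv.end > last.end:
                    merged[-1] = replace(last, end=iv.end)
                continue
        merged.append(
            GenomicInterval(iv.chrom, iv.start, iv.end)
        )
    return [replace(m, name=m.locus_id) for m in merged]


def overlaps_any(
    loci: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    book_ended: bool = False,
) -> list[bool]:
    """For each locus, whether it overlaps at least one peak.

    Per-chromosome binary search over peaks sorted by start, with a running
    prefix maximum of peak ends; O(log m) per locus.
    """
    from bisect import bisect_left, bisect_right

    by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    for c in {p.chrom for p in peaks}:
        ps = sorted((p.start, p.end) for p in peaks if p.chrom == c)
        starts = [s for s, _ in ps]
        prefix_max_end: list[int] = []
        m = -1
        for _, e in ps:
            m = max(m, e)
            prefix_max_end.append(m)
        by_chrom[c] = (starts, prefix_max_end)

    out = [False] * len(loci)
    for i, loc in enumerate(loci):
        if loc.chrom not in by_chrom:
            continue
        starts, pme = by_chrom[loc.chrom]
        # peaks that start early enough to possibly overlap
        if book_ended:
            k = bisect_right(starts, loc.end)
        else:
            k = bisect_left(starts, loc.end)
        if k == 0:
            continue
        max_end = pme[k - 1]
        out[i] = max_end >= loc.start if book_ended else max_end > loc.start
    return out


def pair_by_max_overlap(
    loci_a: Sequence[GenomicInterval], loci_b: Sequence[GenomicInterval]
) -> list[int]:
    """For each interval in ``loci_a``, index of the maximal-overlap partner
    in ``loci_b`` (-1 if none overlaps).  Ties broken toward the leftmost
    (smallest start, then smallest index) partner.
    """
    from bisect import bisect_left

    out = [-1] * len(loci_a)
    by_chrom: dict[str, list[tuple[int, GenomicInterval]]] = {}
    for j, b in enumerate(loci_b):
        by_chrom.setdefault(b.chrom, []).append((j, b))
    max_len: dict[str, int] = {}
    starts_by_chrom: dict[str, list[int]] = {}
    for c in by_chrom:
        by_chrom[c].sort(key=lambda t: (t[1].start, t[0]))
        max_len[c] = max(len(b) for _, b in by_chrom[c])
        starts_by_chrom[c] = [b.start for _, b in by_chrom[c]]
    for i, a in enumerate(loci_a):
        if a.chrom not in by_chrom:
            continue
        cands = by_chrom[a.chrom]
        lo = bisect_left(starts_by_chrom[a.chrom], a.start - max_len[a.chrom])
        best_len, best_j = 0, -1
        for j, b in cands[lo:]:
            if b.start >= a.end:
                break
            ol = overlap_length(a, b)
            if ol > best_len:
                best_len, best_j = ol, j
        out[i] = best_j
    return out
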