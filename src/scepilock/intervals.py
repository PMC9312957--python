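"""Genomic intervals in 0-based half-open (BED) coordinates."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span.

    The unit of peaks, negative fragments, motif placements and key regions.
    Ordering is (chrom, start, end) so sorted lists of intervals follow the
    conventional BED sort order.
    """

    chrom: str
    start: int
    end: int
    name: str | None = field(default=None, compare=False)
    strand: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two spans share >= 1 bp."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        """True if 0-based position `pos` lies inside the span."""
        return chrom == self.chrom and self.start <= pos < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def distance_to_point(self, pos: int) -> int:
        """bp distance from a 0-based position to the nearest covered base (0 if inside)."""
        if pos < self.start:
            return self.start - pos
        if pos >= self.end:
            return pos - self.end + 1
        return 0


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def merge_adjacent(intervals: Iterable[GenomicInterval]) -> Iterator[GenomicInterval]:
    """Merge book-ended or overlapping intervals on the same chromosome.

    Input must be sorted by (chrom, start).
    """
    current: GenomicInterval | None = None
    for iv in intervals:
        if current is not None and iv.chrom == current.chrom and iv.start <= current.end:
            if iv.end > current.end:
                current = GenomicInterval(current.chrom, current.start, iv.end)
            continue
        if current is not None:
            yield current
        current = GenomicInterval(iv.chrom, iv.start, iv.end)
    if current is not None:
        yield current
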