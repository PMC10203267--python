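"""Genomic intervals and interval algebra.

All coordinates inside the package are 1-based and inclusive on both ends,
matching the convention of printed genome spans (``Chr14:39979216-52678755``).
BED and bedGraph files are converted at the I/O boundary (:mod:`zwscan.io_formats`).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based, fully closed genomic span.

    ``length_bp`` is the number of bases covered (``end - start + 1``).
    Megabase *reporting* instead uses ``end - start`` (see :func:`span_mb`),
    the convention used when quoting chromosome spans such as
    ``39979216-52678755 -> 12.70 Mb``.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def expand(self, flank: int, chrom_length: int | None = None) -> "GenomicInterval":
        """Widen by ``flank`` bp on both sides, clipped to [1, chrom_length]."""
        start = max(1, self.start - flank)
        end = self.end + flank
        if chrom_length is not None:
            end = min(end, chrom_length)
        return GenomicInterval(self.chrom, start, end)


def span_mb(iv: GenomicInterval, ndigits: int = 2) -> float:
    """Span in Mb, computed as (end - start)/1e6 and rounded half-up.

    This reproduces printed span arithmetic: Chr14:39979216-52678755 -> 12.70.
    """
    mb = Decimal(iv.end - iv.start) / Decimal(10**6)
    q = Decimal(1).scaleb(-ndigits)
    return float(mb.quantize(q, rounding=ROUND_HALF_UP))


def sort_intervals(ivs: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    return sorted(ivs, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    ivs: Iterable[GenomicInterval], max_gap: int = 0
) -> list[GenomicInterval]:
    """Merge overlapping (or ``<= max_gap``-separated) intervals per chromosome."""
    out: list[GenomicInterval] = []
    for iv in sort_intervals(ivs):
        if out and iv.chrom == out[-1].chrom and iv.start <= out[-1].end + max_gap + 1:
            last = out.pop()
            out.append(GenomicInterval(last.chrom, last.start, max(last.end, iv.end)))
        else:
            out.append(iv)
    return out


def intersect_interval_sets(
    a: Sequence[GenomicInterval], b: Sequence[GenomicInterval]
) -> list[tuple[GenomicInterval, int, int]]:
    """All pairwise intersections of two interval sets.

    Returns tuples ``(intersection, index_in_a, index_in_b)`` so callers can
    keep provenance of which members support each piece.
    """
    out: list[tuple[GenomicInterval, int, int]] = []
    for i, iv_a in enumerate(a):
        for j, iv_b in enumerate(b):
            x = iv_a.intersect(iv_b)
            if x is not None:
                out.append((x, i, j))
    return out


def total_bp(ivs: Iterable[GenomicInterval]) -> int:
    return sum(iv.length_bp for iv in merge_intervals(ivs))


def sliding_windows(
    chrom: str, chrom_length: int, window: int, step: int
) -> list[GenomicInterval]:
    """Tile [1, chrom_length] with sliding windows (last window clipped)."""
    if window <= 0 or step <= 0:
        raise ValueError("window and step must be positive")
    out = []
    start = 1
    while start <= chrom_length:
        out.append(GenomicInterval(chrom, start, min(start + window - 1, chrom_length)))
        if start + window - 1 >= chrom_length:
            break
        start += step
    return out
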