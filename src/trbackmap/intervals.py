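"""Genomic intervals and interval arithmetic.

All coordinates are BED-style: 0-based, half-open. Inclusive coordinate
systems (CCDS, VCF output) are converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open span ``[start, end)`` on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start in {self.chrom}:{self.start}-{self.end}")
        if self.end <= self.start:
            raise ValueError(f"empty/inverted interval {self.chrom}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read the first three columns of a BED file (track/browser lines skipped)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                fields = line.split()
            out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def pad_and_merge(
    targets: Sequence[GenomicInterval],
    pad: int,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[GenomicInterval]:
    """Extend every target by ``pad`` bases on both sides and merge overlaps.

    Padding is clipped at position 0 and, when ``chrom_lengths`` is given, at
    the chromosome end. Overlapping or bookended padded intervals collapse
    into a single run, so the result is sorted and strictly non-overlapping.

    Raises ``ValueError`` naming the offending interval if a target lies on
    an unknown chromosome or beyond its end.
    """
    if pad < 0:
        raise ValueError("pad must be non-negative")
    padded: list[GenomicInterval] = []
    for iv in targets:
        if chrom_lengths is not None:
            if iv.chrom not in chrom_lengths:
                raise ValueError(f"interval {iv.chrom}:{iv.start}-{iv.end}: unknown chromosome")
            if iv.end > chrom_lengths[iv.chrom]:
                raise ValueError(
                    f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                    f"length {chrom_lengths[iv.chrom]}"
                )
        lo = max(0, iv.start - pad)
        hi = iv.end + pad
        if chrom_lengths is not None:
            hi = min(hi, chrom_lengths[iv.chrom])
        padded.append(GenomicInterval(iv.chrom, lo, hi))

    padded.sort()
    merged: list[GenomicInterval] = []
    for iv in padded:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(iv)
    return merged


def total_length(intervals: Iterable[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)
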