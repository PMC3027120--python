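"""Base-wise coverage ("signal map") computation.

Coverage over an interval is the per-base count of uniquely mapped reads
whose reference-consuming CIGAR blocks cover that base (N and D gaps are
not covered).  Whole chromosomes are computed in a single event-based
sweep: +1 at every aligned-block start, -1 at every block end, then a
prefix sum — linear in the number of reads plus the chromosome length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .alignio import SampleAlignment


@dataclass
class CoverageTrack:
    """Dense per-base signal over [start, start + len(values)) on a chromosome."""

    chrom: str
    start: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)

    @property
    def end(self) -> int:
        return self.start + len(self.values)

    def slice(self, start: int, end: int) -> "CoverageTrack":
        if start < self.start or end > self.end or start >= end:
            raise ValueError(
                f"slice [{start}, {end}) outside track [{self.start}, {self.end})"
            )
        return CoverageTrack(self.chrom, start, self.values[start - self.start : end - self.start])

    def same_interval(self, other: "CoverageTrack") -> bool:
        return (
            self.chrom == other.chrom
            and self.start == other.start
            and len(self.values) == len(other.values)
        )


def coverage_vector(
    sample: SampleAlignment, chrom: str, start: int, end: int
) -> CoverageTrack:
    """Per-base unique-read coverage over the window [start, end).

    Candidate reads are located by binary search on the start-sorted list:
    reads starting at or after ``end``, or ending at or before ``start``
    (bounded via the maximum read span), are excluded without inspection.
    """
    if start >= end:
        raise ValueError(f"require start < end, got [{start}, {end})")
    diff = np.zeros(end - start + 1, dtype=np.int64)
    reads = sample.reads_by_chrom.get(chrom, [])
    if reads:
        starts = sample.starts(chrom)
        lo = int(np.searchsorted(starts, start - sample.max_span(chrom), side="left"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for read in reads[lo:hi]:
            for bs, be in read.blocks():
                bs, be = max(bs, start), min(be, end)
                if bs < be:
                    diff[bs - start] += 1
                    diff[be - start] -= 1
    return CoverageTrack(chrom, start, np.cumsum(diff[:-1]))


def genome_signal_map(
    sample: SampleAlignment, chrom_sizes: Mapping[str, int] | None = None
) -> dict[str, CoverageTrack]:
    """Whole-genome signal map: one dense track per chromosome.

    Sizes default to the SAM/BAM header (@SQ LN); every read must fit
    within its declared chromosome.
    """
    sizes = dict(chrom_sizes) if chrom_sizes is not None else dict(sample.chrom_sizes)
    for chrom in sample.reads_by_chrom:
        if chrom not in sizes:
            raise ValueError(f"chromosome {chrom!r} missing from chromosome sizes")
    tracks: dict[str, CoverageTrack] = {}
    for chrom, size in sizes.items():
        reads = sample.reads_by_chrom.get(chrom, [])
        if reads:
            last = reads[-1]
            bad = max(reads, key=lambda r: r.end)
            if bad.end > size:
                raise ValueError(
                    f"read at {chrom}:{bad.start} (CIGAR {bad.cigar}) extends to "
                    f"{bad.end}, beyond declared size {size}"
                )
            del last
        diff = np.zeros(size + 1, dtype=np.int64)
        bstarts, bends = sample.block_arrays(chrom)
        np.add.at(diff, bstarts, 1)
        np.add.at(diff, bends, -1)
        tracks[chrom] = CoverageTrack(chrom, 0, np.cumsum(diff[:-1]))
    return tracks


def average_signal(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Element-wise arithmetic mean of tracks over one shared interval."""
    if not tracks:
        raise ValueError("at least one track required")
    first = tracks[0]
    for t in tracks[1:]:
        if not first.same_interval(t):
            raise ValueError(
                f"mismatched intervals: {first.chrom}:{first.start}+{len(first.values)} "
                f"vs {t.chrom}:{t.start}+{len(t.values)}"
            )
    stacked = np.stack([t.values.astype(np.float64) for t in tracks])
    return CoverageTrack(first.chrom, first.start, stacked.mean(axis=0))


def differential_signal(
    group_a: Sequence[CoverageTrack], group_b: Sequence[CoverageTrack]
) -> CoverageTrack:
    """Base-wise difference of group averages: mean(A) - mean(B)."""
    avg_a = average_signal(group_a)
    avg_b = average_signal(group_b)
    if not avg_a.same_interval(avg_b):
        raise ValueError("group intervals do not match")
    return CoverageTrack(avg_a.chrom, avg_a.start, avg_a.values - avg_b.values)


def differential_signal_map(
    group_a: Sequence[dict[str, CoverageTrack]],
    group_b: Sequence[dict[str, CoverageTrack]],
) -> dict[str, CoverageTrack]:
    """Per-chromosome differential map from two groups of whole-genome maps."""
    chroms = set()
    for m in list(group_a) + list(group_b):
        chroms.update(m)
    out = {}
    for chrom in sorted(chroms):
        out[chrom] = differential_signal(
            [m[chrom] for m in group_a], [m[chrom] for m in group_b]
        )
    return out


def read_chrom_sizes(path: str) -> dict[str, int]:
    """Two-column TSV of chromosome name and length; '#' comments skipped."""
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split("\t")[:2] if "\t" in line else line.split()[:2]
            sizes[name] = int(length)
    return sizes
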