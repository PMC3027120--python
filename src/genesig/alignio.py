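"""SAM/BAM and junction-BED input, uniqueness filtering, sorting and merging.

Reads are kept as start-sorted per-chromosome lists storing only what the
downstream counting and pileup steps need: start position, CIGAR, mapping
quality and flags.  "Uniquely mapped" follows the dominant aligner
convention: the NH tag when present (NH == 1), otherwise MAPQ > 0.
"""

from __future__ import annotations

import heapq
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .annotation import ExonInterval

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

FLAG_UNMAPPED = 0x4
FLAG_SECONDARY = 0x100
FLAG_SUPPLEMENTARY = 0x800


class AlignmentInputError(ValueError):
    pass


def cigar_reference_blocks(cigar: str, start: int) -> list[tuple[int, int]]:
    """Reference-consuming aligned blocks [start, end) of a CIGAR string.

    M/=/X extend the current block; N and D advance the reference without
    coverage (D bases are not counted as covered); I/S/H/P consume no
    reference.
    """
    blocks: list[tuple[int, int]] = []
    pos = start
    block_start = None
    for m in _CIGAR_RE.finditer(cigar):
        length, op = int(m.group(1)), m.group(2)
        if op in "M=X":
            if block_start is None:
                block_start = pos
            pos += length
        elif op in "DN":
            if op == "D" and block_start is not None:
                # close the covered block across the deletion
                blocks.append((block_start, pos))
                block_start = None
            elif op == "N" and block_start is not None:
                blocks.append((block_start, pos))
                block_start = None
            pos += length
    if block_start is not None:
        blocks.append((block_start, pos))
    return blocks


def cigar_reference_length(cigar: str) -> int:
    return sum(
        int(m.group(1)) for m in _CIGAR_RE.finditer(cigar) if m.group(2) in "MDN=X"
    )


@dataclass(slots=True)
class AlignedRead:
    chrom: str
    start: int
    cigar: str
    mapq: int
    flags: int
    unique: bool

    @property
    def reference_length(self) -> int:
        return cigar_reference_length(self.cigar)

    @property
    def end(self) -> int:
        return self.start + self.reference_length

    def blocks(self) -> list[tuple[int, int]]:
        return cigar_reference_blocks(self.cigar, self.start)


@dataclass(slots=True)
class JunctionRead:
    """A junction-spanning read: two anchor blocks separated by an intron gap."""

    chrom: str
    left_block: ExonInterval
    right_block: ExonInterval
    count: int = 1

    def __post_init__(self) -> None:
        if self.left_block.end > self.right_block.start:
            raise ValueError(
                "junction anchors must be gap-separated: "
                f"left ends at {self.left_block.end}, right starts at {self.right_block.start}"
            )
        if self.count < 1:
            raise ValueError("junction count must be >= 1")


def is_unique(mapq: int, nh: int | None) -> bool:
    """Uniqueness rule: NH tag takes precedence; fallback is MAPQ > 0."""
    if nh is not None:
        return nh == 1
    return mapq > 0


@dataclass
class SampleAlignment:
    """A sample's uniquely mapped reads, start-sorted per chromosome."""

    sample_id: str
    reads_by_chrom: dict[str, list[AlignedRead]] = field(default_factory=dict)
    n_total_records: int = 0
    chrom_sizes: dict[str, int] = field(default_factory=dict)
    _start_arrays: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    _block_arrays: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )
    _max_span: dict[str, int] = field(default_factory=dict, repr=False)

    @property
    def n_unique(self) -> int:
        return sum(len(v) for v in self.reads_by_chrom.values())

    def add(self, read: AlignedRead) -> None:
        self.reads_by_chrom.setdefault(read.chrom, []).append(read)
        self._start_arrays.pop(read.chrom, None)
        self._block_arrays.pop(read.chrom, None)
        self._max_span.pop(read.chrom, None)

    def finalize(self) -> "SampleAlignment":
        """Stable-sort each per-chromosome list by start position."""
        for lst in self.reads_by_chrom.values():
            lst.sort(key=lambda r: r.start)  # Timsort: stable
        self._start_arrays.clear()
        self._block_arrays.clear()
        self._max_span.clear()
        return self

    def starts(self, chrom: str) -> np.ndarray:
        if chrom not in self._start_arrays:
            reads = self.reads_by_chrom.get(chrom, [])
            self._start_arrays[chrom] = np.fromiter(
                (r.start for r in reads), dtype=np.int64, count=len(reads)
            )
        return self._start_arrays[chrom]

    def block_arrays(self, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """Concatenated aligned-block (starts, ends) over all reads on chrom."""
        if chrom not in self._block_arrays:
            starts: list[int] = []
            ends: list[int] = []
            for r in self.reads_by_chrom.get(chrom, []):
                for s, e in r.blocks():
                    starts.append(s)
                    ends.append(e)
            self._block_arrays[chrom] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )
        return self._block_arrays[chrom]

    def max_span(self, chrom: str) -> int:
        if chrom not in self._max_span:
            reads = self.reads_by_chrom.get(chrom, [])
            self._max_span[chrom] = max((r.reference_length for r in reads), default=0)
        return self._max_span[chrom]


def load_exon_alignments(path: str | Path, sample_id: str | None = None) -> SampleAlignment:
    """Load a SAM/BAM file, keeping uniquely mapped primary records.

    Unmapped and non-unique records are excluded from the per-chromosome
    lists but counted in ``n_total_records``.  Chromosome sizes are taken
    from the @SQ header lines.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    sample = SampleAlignment(sample_id=sample_id)
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        sample.chrom_sizes = dict(zip(fh.references, fh.lengths))
        for i, rec in enumerate(fh):
            sample.n_total_records += 1
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            try:
                nh = rec.get_tag("NH")
            except KeyError:
                nh = None
            unique = is_unique(rec.mapping_quality, nh)
            if not unique:
                continue
            if rec.cigarstring is None:
                raise AlignmentInputError(f"record {i}: mapped read without CIGAR")
            sample.add(
                AlignedRead(
                    chrom=rec.reference_name,
                    start=rec.reference_start,
                    cigar=rec.cigarstring,
                    mapq=rec.mapping_quality,
                    flags=rec.flag,
                    unique=True,
                )
            )
    return sample.finalize()


def load_junction_reads(
    path: str | Path,
    count_mode: str = "score",
    allow_bed6: bool = False,
) -> list[JunctionRead]:
    """Load junction reads from a BED file (junction-mapper output).

    BED12 records must have exactly 2 blocks, which become the left and
    right anchors.  In ``score`` mode a positive score column is the number
    of supporting reads; in ``one`` mode every record counts 1.  BED6 lines
    are rejected unless ``allow_bed6``, in which case single-base degenerate
    anchors at the interval ends are used.
    """
    if count_mode not in ("score", "one"):
        raise ValueError(f"unknown junction count mode {count_mode!r}")
    junctions: list[JunctionRead] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            score = 0
            if len(fields) > 4:
                try:
                    score = int(float(fields[4]))
                except ValueError:
                    score = 0
            count = score if (count_mode == "score" and score >= 1) else 1
            if len(fields) >= 12:
                n_blocks = int(fields[9])
                if n_blocks != 2:
                    raise AlignmentInputError(
                        f"line {lineno}: junction BED12 record must have exactly 2 blocks, "
                        f"got {n_blocks}"
                    )
                sizes = [int(t) for t in fields[10].rstrip(",").split(",")]
                offsets = [int(t) for t in fields[11].rstrip(",").split(",")]
                left = ExonInterval(chrom, start + offsets[0], start + offsets[0] + sizes[0])
                right = ExonInterval(chrom, start + offsets[1], start + offsets[1] + sizes[1])
            elif allow_bed6:
                left = ExonInterval(chrom, start, start + 1)
                right = ExonInterval(chrom, end - 1, end)
            else:
                raise AlignmentInputError(
                    f"line {lineno}: junction record has no blocks to anchor "
                    "(BED12 required; pass allow_bed6 for degenerate anchors)"
                )
            junctions.append(JunctionRead(chrom, left, right, count))
    return junctions


def _open_alignment(path: str | Path) -> pysam.AlignmentFile:
    return pysam.AlignmentFile(str(path), check_sq=False)


def _write_mode(path: str | Path) -> str:
    return "wb" if str(path).endswith(".bam") else "wh"


def sort_alignment_file(path_in: str | Path, path_out: str | Path) -> None:
    """Coordinate-sort a SAM/BAM file with a stable sort.

    Order is (chromosome index per the header, start position); records with
    equal keys keep their input order, and unmapped records go last in input
    order.
    """
    with _open_alignment(path_in) as fh:
        header = fh.header.to_dict()
        n_refs = fh.nreferences
        records = list(fh)
    records.sort(
        key=lambda r: (
            n_refs if r.reference_id < 0 else r.reference_id,
            r.reference_start if r.reference_id >= 0 else 0,
        )
    )
    header.setdefault("HD", {})
    header["HD"]["VN"] = header["HD"].get("VN", "1.6")
    header["HD"]["SO"] = "coordinate"
    with pysam.AlignmentFile(str(path_out), _write_mode(path_out), header=header) as out:
        for rec in records:
            out.write(rec)


def _compatible_references(headers: Sequence[dict]) -> list[dict]:
    sqs = [h.get("SQ", []) for h in headers]
    first = [(sq["SN"], sq["LN"]) for sq in sqs[0]]
    for other in sqs[1:]:
        if [(sq["SN"], sq["LN"]) for sq in other] != first:
            raise AlignmentInputError(
                "cannot merge: incompatible reference dictionaries across inputs"
            )
    return sqs[0]


def merge_alignment_files(paths_in: Sequence[str | Path], path_out: str | Path) -> None:
    """Merge coordinate-sorted SAM/BAM files into one sorted file.

    A k-way heap merge on (chromosome index, start, input index) keeps the
    result sorted and stable: equal keys preserve input-file order.
    """
    handles = [_open_alignment(p) for p in paths_in]
    try:
        headers = [fh.header.to_dict() for fh in handles]
        _compatible_references(headers)
        header = headers[0]
        header.setdefault("HD", {})
        header["HD"]["VN"] = header["HD"].get("VN", "1.6")
        header["HD"]["SO"] = "coordinate"
        n_refs = handles[0].nreferences

        def keyed(fh: pysam.AlignmentFile, idx: int):
            for rec in fh:
                ref = n_refs if rec.reference_id < 0 else rec.reference_id
                pos = rec.reference_start if rec.reference_id >= 0 else 0
                yield (ref, pos, idx), rec

        streams = [keyed(fh, i) for i, fh in enumerate(handles)]
        with pysam.AlignmentFile(str(path_out), _write_mode(path_out), header=header) as out:
            for _key, rec in heapq.merge(*streams, key=lambda kv: kv[0]):
                out.write(rec)
    finally:
        for fh in handles:
            fh.close()


def total_junction_count(junctions: Iterable[JunctionRead]) -> int:
    return sum(j.count for j in junctions)
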