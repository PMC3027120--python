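"""Gene-annotation parsing and genomic-position classification.

Gene models are read from BED12 or refFlat-style tab-delimited files into an
:class:`AnnotationIndex`, a per-chromosome map of start-sorted genes.  All
coordinates are 0-based half-open internally; conversion to and from 1-based
conventions happens only at file boundaries.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal


class AnnotationError(ValueError):
    """Raised for malformed annotation records (message names the line)."""


@dataclass(frozen=True, slots=True)
class ExonInterval:
    """A half-open exon interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not 0 <= self.start < self.end:
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) pairs into a disjoint sorted union."""
    merged: list[tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass(slots=True)
class GeneModel:
    """A gene: chromosome, strand, and its exon structure.

    ``exon_union_length`` is the number of bases in the union of the exons
    (overlapping exons counted once) — the gene length L used as the
    kilobase normalizer in RPKM.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[ExonInterval]

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: exons must be non-empty")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: unknown strand {self.strand!r}")
        if any(e.chrom != self.chrom for e in self.exons):
            raise ValueError(f"gene {self.gene_id}: exon on wrong chromosome")
        self.exons = sorted(self.exons, key=lambda e: (e.start, e.end))

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)

    @property
    def exon_union(self) -> list[tuple[int, int]]:
        return merge_intervals((e.start, e.end) for e in self.exons)

    @property
    def exon_union_length(self) -> int:
        return sum(e - s for s, e in self.exon_union)


@dataclass
class AnnotationIndex:
    """Genes keyed by chromosome, each list sorted by gene span start."""

    genes_by_chrom: dict[str, list[GeneModel]] = field(default_factory=dict)
    # lazily built per-chromosome merged interval caches for classification
    _exonic_flat: dict[str, list[int]] = field(default_factory=dict, repr=False)
    _genic_flat: dict[str, list[int]] = field(default_factory=dict, repr=False)

    @classmethod
    def from_genes(cls, genes: Iterable[GeneModel]) -> "AnnotationIndex":
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for lst in by_chrom.values():
            lst.sort(key=lambda g: (g.start, g.end))
        return cls(genes_by_chrom=by_chrom)

    def genes(self) -> Iterator[GeneModel]:
        for chrom in self.genes_by_chrom:
            yield from self.genes_by_chrom[chrom]

    def n_genes(self) -> int:
        return sum(len(v) for v in self.genes_by_chrom.values())

    def _flats(self, chrom: str) -> tuple[list[int], list[int]]:
        if chrom not in self._exonic_flat:
            genes = self.genes_by_chrom.get(chrom, [])
            exonic = merge_intervals(
                (e.start, e.end) for g in genes for e in g.exons
            )
            genic = merge_intervals((g.start, g.end) for g in genes)
            self._exonic_flat[chrom] = [x for iv in exonic for x in iv]
            self._genic_flat[chrom] = [x for iv in genic for x in iv]
        return self._exonic_flat[chrom], self._genic_flat[chrom]

    def classify_position(self, chrom: str, pos: int) -> str:
        """Label a base as ``exonic``, ``intronic`` or ``intergenic``.

        Exonic takes precedence over intronic when genes overlap; an unknown
        chromosome is intergenic.
        """
        if pos < 0:
            raise ValueError("pos must be >= 0")
        exonic_flat, genic_flat = self._flats(chrom)
        if bisect.bisect_right(exonic_flat, pos) % 2 == 1:
            return "exonic"
        if bisect.bisect_right(genic_flat, pos) % 2 == 1:
            return "intronic"
        return "intergenic"


def classify_position(index: AnnotationIndex, chrom: str, pos: int) -> str:
    return index.classify_position(chrom, pos)


def _split_csv_ints(text: str, what: str, lineno: int) -> list[int]:
    try:
        return [int(tok) for tok in text.rstrip(",").split(",") if tok != ""]
    except ValueError as exc:
        raise AnnotationError(f"line {lineno}: bad {what} field {text!r}") from exc


def _dedupe_gene_ids(genes: list[GeneModel]) -> list[GeneModel]:
    # duplicated gene_ids become distinct loci suffixed by index
    from collections import Counter

    counts = Counter(g.gene_id for g in genes)
    seen: Counter = Counter()
    out = []
    for g in genes:
        gid = g.gene_id
        if counts[gid] > 1:
            seen[gid] += 1
            g = GeneModel(f"{gid}_locus{seen[gid]}", g.chrom, g.strand, list(g.exons))
        out.append(g)
    return out


def parse_bed12_gene(fields: list[str], lineno: int) -> GeneModel:
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name = fields[3] if len(fields) > 3 else f"record{lineno}"
    strand = fields[5] if len(fields) > 5 else "+"
    if strand not in ("+", "-"):
        raise AnnotationError(f"line {lineno}: unknown strand symbol {strand!r}")
    if len(fields) >= 12:
        n_blocks = int(fields[9])
        sizes = _split_csv_ints(fields[10], "blockSizes", lineno)
        offsets = _split_csv_ints(fields[11], "blockStarts", lineno)
        if len(sizes) != n_blocks or len(offsets) != n_blocks:
            raise AnnotationError(
                f"line {lineno}: blockSizes/blockStarts arity mismatch "
                f"(blockCount={n_blocks}, sizes={len(sizes)}, starts={len(offsets)})"
            )
        exons = [
            ExonInterval(chrom, start + off, start + off + size)
            for off, size in zip(offsets, sizes)
        ]
    else:
        exons = [ExonInterval(chrom, start, end)]
    return GeneModel(name, chrom, strand, exons)


def parse_refflat_gene(fields: list[str], lineno: int) -> GeneModel:
    # geneName name chrom strand txStart txEnd cdsStart cdsEnd exonCount exonStarts exonEnds
    if len(fields) < 11:
        raise AnnotationError(f"line {lineno}: refFlat record needs 11 columns, got {len(fields)}")
    gene_name, _name, chrom, strand = fields[0], fields[1], fields[2], fields[3]
    if strand not in ("+", "-"):
        raise AnnotationError(f"line {lineno}: unknown strand symbol {strand!r}")
    n_exons = int(fields[8])
    starts = _split_csv_ints(fields[9], "exonStarts", lineno)
    ends = _split_csv_ints(fields[10], "exonEnds", lineno)
    if len(starts) != n_exons or len(ends) != n_exons:
        raise AnnotationError(f"line {lineno}: exonStarts/exonEnds arity mismatch")
    exons = [ExonInterval(chrom, s, e) for s, e in zip(starts, ends)]
    return GeneModel(gene_name, chrom, strand, exons)


def parse_annotation(path: str | Path, format: Literal["bed12", "refflat"] = "bed12") -> AnnotationIndex:
    """Parse a BED12 or refFlat annotation file into an :class:`AnnotationIndex`."""
    if format not in ("bed12", "refflat"):
        raise ValueError(f"unknown annotation format {format!r}")
    parser = parse_bed12_gene if format == "bed12" else parse_refflat_gene
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            try:
                genes.append(parser(fields, lineno))
            except AnnotationError:
                raise
            except (ValueError, IndexError) as exc:
                raise AnnotationError(f"line {lineno}: malformed record: {exc}") from exc
    return AnnotationIndex.from_genes(_dedupe_gene_ids(genes))


def write_bed12(index: AnnotationIndex, path: str | Path) -> None:
    """Serialize gene models back to BED12 (exons as blocks)."""
    with open(path, "w") as fh:
        for gene in index.genes():
            start, end = gene.start, gene.end
            blocks = gene.exon_union
            sizes = ",".join(str(e - s) for s, e in blocks) + ","
            offsets = ",".join(str(s - start) for s, e in blocks) + ","
            fh.write(
                "\t".join(
                    [
                        gene.chrom,
                        str(start),
                        str(end),
                        gene.gene_id,
                        "0",
                        gene.strand,
                        str(start),
                        str(end),
                        "0",
                        str(len(blocks)),
                        sizes,
                        offsets,
                    ]
                )
                + "\n"
            )


def read_bed_intervals(path: str | Path) -> list[tuple[str, str, int, int]]:
    """Read a BED6 (or BED3+) file of plain intervals, e.g. 3'-UTRs.

    Returns (interval_id, chrom, start, end) tuples with 0-based half-open
    coordinates; '#'-prefixed comment lines are skipped.
    """
    out: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith(("track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 3:
                raise AnnotationError(f"line {lineno}: BED interval needs >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else f"interval{lineno}"
            out.append((name, chrom, start, end))
    return out
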