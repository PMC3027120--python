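"""Alignment QC report: uniqueness percentage and genomic-region breakdown.

Each uniquely mapped read is classified at its start position as exonic,
intronic or intergenic against the gene annotation; a read starting in an
exon but running into an intron is exonic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .alignio import SampleAlignment
from .annotation import AnnotationIndex


@dataclass(slots=True)
class AlignmentStats:
    sample_id: str
    n_total: int
    n_unique: int
    n_exonic: int
    n_intronic: int
    n_intergenic: int

    @property
    def pct_unique(self) -> float:
        return 100.0 * self.n_unique / self.n_total if self.n_total else 0.0

    @property
    def pct_exonic(self) -> float:
        return 100.0 * self.n_exonic / self.n_unique if self.n_unique else 0.0

    @property
    def pct_intronic(self) -> float:
        return 100.0 * self.n_intronic / self.n_unique if self.n_unique else 0.0

    @property
    def pct_intergenic(self) -> float:
        return 100.0 * self.n_intergenic / self.n_unique if self.n_unique else 0.0

    def to_text(self) -> str:
        lines = [
            f"sample: {self.sample_id}",
            f"total_records: {self.n_total}",
            f"uniquely_mapped: {self.n_unique}",
            f"pct_unique: {self.pct_unique:.1f}",
            f"exonic: {self.n_exonic}",
            f"intronic: {self.n_intronic}",
            f"intergenic: {self.n_intergenic}",
            f"pct_exonic: {self.pct_exonic:.1f}",
            f"pct_intronic: {self.pct_intronic:.1f}",
            f"pct_intergenic: {self.pct_intergenic:.1f}",
        ]
        return "\n".join(lines) + "\n"

    def to_tsv(self) -> str:
        header = (
            "sample\tn_total\tn_unique\tpct_unique\t"
            "n_exonic\tn_intronic\tn_intergenic\t"
            "pct_exonic\tpct_intronic\tpct_intergenic\n"
        )
        row = (
            f"{self.sample_id}\t{self.n_total}\t{self.n_unique}\t{self.pct_unique:.1f}\t"
            f"{self.n_exonic}\t{self.n_intronic}\t{self.n_intergenic}\t"
            f"{self.pct_exonic:.1f}\t{self.pct_intronic:.1f}\t{self.pct_intergenic:.1f}\n"
        )
        return header + row


def alignment_report(sample: SampleAlignment, index: AnnotationIndex) -> AlignmentStats:
    """Classify every unique read at its start and tally region percentages."""
    counts = {"exonic": 0, "intronic": 0, "intergenic": 0}
    for chrom, reads in sample.reads_by_chrom.items():
        for read in reads:
            counts[index.classify_position(chrom, read.start)] += 1
    return AlignmentStats(
        sample_id=sample.sample_id,
        n_total=sample.n_total_records,
        n_unique=sample.n_unique,
        n_exonic=counts["exonic"],
        n_intronic=counts["intronic"],
        n_intergenic=counts["intergenic"],
    )


def write_report(stats: AlignmentStats, text_path: str | Path, tsv_path: str | Path | None = None) -> None:
    Path(text_path).write_text(stats.to_text())
    if tsv_path is not None:
        Path(tsv_path).write_text(stats.to_tsv())
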