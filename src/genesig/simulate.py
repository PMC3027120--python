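"""Deterministic synthetic RNA-seq fixtures: genome annotation, alignments,
junction reads and planted signals.

The generator emulates the inputs the pipeline consumes in practice: a toy
multi-exon gene annotation (BED12), coordinate-sorted single-end SAM files
with uniquely mapped, multi-mapped (NH:i:2) and unmapped records, a
junction-mapper BED of exon-exon junction reads (about 10% of reads, the
fraction typical of mammalian RNA-seq), chromosome sizes, and a truth table
of per-gene read counts.  One pseudo-random stream per concern (gene layout,
per-sample reads), all derived from a single master seed, so identical seeds
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignio import AlignedRead, JunctionRead, SampleAlignment
from .annotation import (
    AnnotationIndex,
    ExonInterval,
    GeneModel,
    merge_intervals,
    write_bed12,
)
from .signalmap import CoverageTrack


@dataclass
class SimulationConfig:
    """Layout and sampling parameters for one synthetic dataset.

    ``dropout`` plants a 3'-UTR-style coverage drop: reads of the named gene
    starting in the trailing ``utr_fraction`` of its span are removed with
    probability ``amplitude``.
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 50_000
    n_genes: int = 20
    exons_per_gene: int = 3
    exon_length: int = 200
    intron_length: int = 300
    intergenic_gap: int = 500
    n_reads: int = 10_000
    read_length: int = 50
    n_samples: int = 3
    frac_junction: float = 0.1
    frac_multimapped: float = 0.05
    frac_unmapped: float = 0.05
    dropout: tuple[str, float, float] | None = None  # (gene_id, utr_fraction, amplitude)

    def __post_init__(self) -> None:
        for name in ("frac_junction", "frac_multimapped", "frac_unmapped"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_junction + self.frac_multimapped + self.frac_unmapped > 1.0:
            raise ValueError("read-class fractions exceed 1")
        for name in (
            "chrom_length",
            "exon_length",
            "intron_length",
            "read_length",
            "n_genes",
            "exons_per_gene",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class SyntheticDataset:
    """In-memory view plus the file paths written by the generator."""

    config: SimulationConfig
    index: AnnotationIndex
    chrom_sizes: dict[str, int]
    annotation_path: Path | None = None
    sam_paths: list[Path] = field(default_factory=list)
    junction_paths: list[Path] = field(default_factory=list)
    chrom_sizes_path: Path | None = None
    truth_path: Path | None = None
    truth: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    # truth key: (sample_id, gene_id) -> (c_exon, c_junction)


def layout_genes(config: SimulationConfig) -> tuple[AnnotationIndex, dict[str, int]]:
    """Place non-overlapping multi-exon genes round-robin across chromosomes."""
    gene_span = (
        config.exons_per_gene * config.exon_length
        + (config.exons_per_gene - 1) * config.intron_length
    )
    sizes = {f"chr{i + 1}": config.chrom_length for i in range(config.n_chromosomes)}
    cursors = {c: config.intergenic_gap for c in sizes}
    genes = []
    for gi in range(config.n_genes):
        chrom = f"chr{gi % config.n_chromosomes + 1}"
        start = cursors[chrom]
        end = start + gene_span
        if end + config.intergenic_gap > sizes[chrom]:
            raise ValueError(
                f"gene layout infeasible: gene {gi} needs [{start}, {end}) on {chrom} "
                f"of length {sizes[chrom]}"
            )
        exons = [
            ExonInterval(
                chrom,
                start + k * (config.exon_length + config.intron_length),
                start + k * (config.exon_length + config.intron_length) + config.exon_length,
            )
            for k in range(config.exons_per_gene)
        ]
        genes.append(GeneModel(f"gene{gi + 1:03d}", chrom, "+", exons))
        cursors[chrom] = end + config.intergenic_gap
    return AnnotationIndex.from_genes(genes), sizes


def _union_positions(gene: GeneModel) -> tuple[list[tuple[int, int]], int]:
    union = gene.exon_union
    return union, sum(e - s for s, e in union)


def _offset_to_pos(union: list[tuple[int, int]], offset: int) -> int:
    for s, e in union:
        if offset < e - s:
            return s + offset
        offset -= e - s
    raise IndexError("offset beyond exon union")


def _allocate_counts(n_reads: int, config: SimulationConfig) -> tuple[int, int, int, int]:
    n_junction = int(round(config.frac_junction * n_reads))
    n_multi = int(round(config.frac_multimapped * n_reads))
    n_unmapped = int(round(config.frac_unmapped * n_reads))
    n_exon = n_reads - n_junction - n_multi - n_unmapped
    return n_exon, n_junction, n_multi, n_unmapped


def _sample_reads(
    config: SimulationConfig,
    index: AnnotationIndex,
    sizes: dict[str, int],
    sample_id: str,
    rng: np.random.Generator,
) -> tuple[list[dict], list[JunctionRead], dict[str, tuple[int, int]]]:
    """Draw one sample's SAM records, junction reads and per-gene truth."""
    genes = list(index.genes())
    unions = [_union_positions(g) for g in genes]
    multi_exon = [i for i, g in enumerate(genes) if len(g.exon_union) >= 2]
    n_exon, n_junction, n_multi, n_unmapped = _allocate_counts(config.n_reads, config)

    dropout_gene, dropout_region = None, None
    if config.dropout is not None:
        gene_id, utr_fraction, amplitude = config.dropout
        matches = [g for g in genes if g.gene_id == gene_id]
        if not matches:
            raise ValueError(f"dropout gene {gene_id!r} not in layout")
        g = matches[0]
        span = g.end - g.start
        dropout_gene = gene_id
        dropout_region = (g.end - int(round(utr_fraction * span)), g.end)

    truth: dict[str, tuple[int, int]] = {g.gene_id: (0, 0) for g in genes}
    records: list[dict] = []
    serial = 0

    def emit_mapped(gene_idx: int, unique: bool) -> bool:
        nonlocal serial
        gene = genes[gene_idx]
        union, ulen = unions[gene_idx]
        offset = int(rng.integers(ulen))
        pos = _offset_to_pos(union, offset)
        if (
            unique
            and dropout_gene == gene.gene_id
            and dropout_region[0] <= pos < dropout_region[1]
            and rng.random() < config.dropout[2]
        ):
            return False  # read removed by the planted drop-out
        pos = min(pos, sizes[gene.chrom] - config.read_length)
        serial += 1
        records.append(
            {
                "qname": f"{sample_id}_r{serial:07d}",
                "flag": 0,
                "chrom": gene.chrom,
                "pos": pos,
                "mapq": 60 if unique else 0,
                "cigar": f"{config.read_length}M",
                "nh": 1 if unique else 2,
            }
        )
        if unique:
            c_a, c_b = truth[gene.gene_id]
            truth[gene.gene_id] = (c_a + 1, c_b)
        return True

    gene_draws = rng.integers(len(genes), size=n_exon)
    for gi in gene_draws:
        emit_mapped(int(gi), unique=True)
    for gi in rng.integers(len(genes), size=n_multi):
        emit_mapped(int(gi), unique=False)
    for _ in range(n_unmapped):
        serial += 1
        records.append(
            {
                "qname": f"{sample_id}_r{serial:07d}",
                "flag": 4,
                "chrom": None,
                "pos": -1,
                "mapq": 0,
                "cigar": None,
                "nh": None,
            }
        )

    # junction reads: one supporting read per draw, anchored on an adjacent
    # exon pair of a multi-exon gene; aggregated per junction afterwards
    half = config.read_length // 2
    junction_support: dict[tuple[str, int, int, int, int], int] = {}
    if n_junction and not multi_exon:
        raise ValueError("frac_junction > 0 requires genes with >= 2 exons")
    for gi in rng.choice(multi_exon, size=n_junction) if n_junction else []:
        gene = genes[int(gi)]
        union = gene.exon_union
        pair = int(rng.integers(len(union) - 1))
        (ls, le), (rs, re) = union[pair], union[pair + 1]
        left = (max(ls, le - half), le)
        right = (rs, min(re, rs + (config.read_length - half)))
        key = (gene.chrom, *left, *right)
        junction_support[key] = junction_support.get(key, 0) + 1
        c_a, c_b = truth[gene.gene_id]
        truth[gene.gene_id] = (c_a, c_b + 1)

    junctions = [
        JunctionRead(
            chrom,
            ExonInterval(chrom, ls, le),
            ExonInterval(chrom, rs, re),
            count,
        )
        for (chrom, ls, le, rs, re), count in sorted(junction_support.items())
    ]
    records.sort(key=lambda r: (r["chrom"] is None, r["chrom"] or "", r["pos"]))
    return records, junctions, truth


def _write_sam(records: list[dict], sizes: dict[str, int], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        for chrom, size in sizes.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{size}\n")
        for r in records:
            if r["flag"] & 4:
                fh.write(f"{r['qname']}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*\n")
            else:
                seq = "A" * int(r["cigar"][:-1])
                fh.write(
                    f"{r['qname']}\t{r['flag']}\t{r['chrom']}\t{r['pos'] + 1}\t"
                    f"{r['mapq']}\t{r['cigar']}\t*\t0\t0\t{seq}\t*\tNH:i:{r['nh']}\n"
                )


def _write_junction_bed(junctions: list[JunctionRead], path: Path) -> None:
    with open(path, "w") as fh:
        for i, j in enumerate(junctions, start=1):
            start, end = j.left_block.start, j.right_block.end
            sizes = f"{j.left_block.length},{j.right_block.length}"
            offsets = f"0,{j.right_block.start - start}"
            fh.write(
                f"{j.chrom}\t{start}\t{end}\tJUNC{i:05d}\t{j.count}\t+\t"
                f"{start}\t{end}\t0\t2\t{sizes}\t{offsets}\n"
            )


def generate_synthetic_dataset(config: SimulationConfig, out_dir: str | Path) -> SyntheticDataset:
    """Write a complete synthetic dataset to ``out_dir``.

    Outputs: ``annotation.bed`` (BED12), ``<sample>.sam`` and
    ``<sample>.junctions.bed`` per sample, ``chrom.sizes`` and ``truth.tsv``
    (per-sample, per-gene exon and junction read counts).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    index, sizes = layout_genes(config)
    ds = SyntheticDataset(config=config, index=index, chrom_sizes=sizes)

    ds.annotation_path = out_dir / "annotation.bed"
    write_bed12(index, ds.annotation_path)

    ds.chrom_sizes_path = out_dir / "chrom.sizes"
    with open(ds.chrom_sizes_path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")

    seeds = np.random.SeedSequence(config.seed).spawn(config.n_samples + 1)
    truth_rows = []
    for si in range(config.n_samples):
        sample_id = f"sample{si + 1}"
        rng = np.random.Generator(np.random.PCG64(seeds[si + 1]))
        records, junctions, truth = _sample_reads(config, index, sizes, sample_id, rng)
        sam_path = out_dir / f"{sample_id}.sam"
        bed_path = out_dir / f"{sample_id}.junctions.bed"
        _write_sam(records, sizes, sam_path)
        _write_junction_bed(junctions, bed_path)
        ds.sam_paths.append(sam_path)
        ds.junction_paths.append(bed_path)
        for gene_id, (c_a, c_b) in truth.items():
            ds.truth[(sample_id, gene_id)] = (c_a, c_b)
            truth_rows.append(f"{sample_id}\t{gene_id}\t{c_a}\t{c_b}\n")

    ds.truth_path = out_dir / "truth.tsv"
    with open(ds.truth_path, "w") as fh:
        if config.dropout is not None:
            gene_id, utr_fraction, amplitude = config.dropout
            fh.write(
                f"# dropout\tgene={gene_id}\tutr_fraction={utr_fraction}\tamplitude={amplitude}\n"
            )
        fh.write("sample_id\tgene_id\tc_exon\tc_junction\n")
        fh.writelines(truth_rows)
    return ds


def random_sample_alignment(
    n_reads: int,
    chrom_length: int = 50_000,
    read_length: int = 50,
    seed: int = 0,
    chrom: str = "chr1",
    sample_id: str = "random",
) -> SampleAlignment:
    """Uniformly placed single-block reads on one chromosome, start-sorted.

    A lightweight in-memory sample for pileup oracle and scaling checks.
    """
    rng = np.random.default_rng(seed)
    starts = np.sort(rng.integers(0, chrom_length - read_length, size=n_reads))
    sample = SampleAlignment(sample_id=sample_id, chrom_sizes={chrom: chrom_length})
    cigar = f"{read_length}M"
    sample.reads_by_chrom[chrom] = [
        AlignedRead(chrom, int(s), cigar, 60, 0, True) for s in starts
    ]
    return sample


def region_position_pools(
    index: AnnotationIndex, chrom_sizes: dict[str, int], margin: int = 0
) -> dict[str, list[tuple[str, int, int]]]:
    """Exonic/intronic/intergenic interval pools over the declared genome."""
    pools: dict[str, list[tuple[str, int, int]]] = {
        "exonic": [],
        "intronic": [],
        "intergenic": [],
    }
    for chrom, size in chrom_sizes.items():
        genes = index.genes_by_chrom.get(chrom, [])
        exonic = merge_intervals((e.start, e.end) for g in genes for e in g.exons)
        genic = merge_intervals((g.start, g.end) for g in genes)
        pools["exonic"].extend((chrom, s, e) for s, e in exonic)

        def complement(intervals, lo, hi):
            out, cur = [], lo
            for s, e in intervals:
                if s > cur:
                    out.append((cur, min(s, hi)))
                cur = max(cur, e)
            if cur < hi:
                out.append((cur, hi))
            return [(s, e) for s, e in out if s < e]

        for s, e in complement(exonic, 0, size - margin):
            # intronic where inside a gene span, intergenic otherwise
            for gs, ge in genic:
                is_, ie = max(s, gs), min(e, ge)
                if is_ < ie:
                    pools["intronic"].append((chrom, is_, ie))
            pieces = complement(genic, s, e)
            pools["intergenic"].extend((chrom, ps, pe) for ps, pe in pieces)
    return pools


def simulate_classified_reads(
    index: AnnotationIndex,
    chrom_sizes: dict[str, int],
    n_exonic: int,
    n_intronic: int,
    n_intergenic: int,
    read_length: int = 50,
    seed: int = 0,
    sample_id: str = "planted",
) -> SampleAlignment:
    """A sample with an exactly planted exonic/intronic/intergenic start mix."""
    rng = np.random.default_rng(seed)
    pools = region_position_pools(index, chrom_sizes, margin=read_length)
    sample = SampleAlignment(sample_id=sample_id, chrom_sizes=dict(chrom_sizes))
    for label, n in (
        ("exonic", n_exonic),
        ("intronic", n_intronic),
        ("intergenic", n_intergenic),
    ):
        intervals = pools[label]
        if n and not intervals:
            raise ValueError(f"no {label} positions available in this layout")
        widths = np.array([e - s for _, s, e in intervals], dtype=np.float64)
        for pick in rng.choice(len(intervals), size=n, p=widths / widths.sum()):
            chrom, s, e = intervals[int(pick)]
            pos = int(rng.integers(s, e))
            sample.add(AlignedRead(chrom, pos, f"{read_length}M", 60, 0, True))
            sample.n_total_records += 1
    return sample.finalize()


def simulate_differential_utr_map(
    n_utrs: int = 10,
    utr_length: int = 400,
    gap: int = 100,
    dropout_utr: int = 0,
    dropout_fraction: float = 0.4,
    amplitude: float = 3.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    chrom: str = "chrD",
) -> tuple[dict[str, CoverageTrack], list[tuple[str, str, int, int]], int]:
    """A differential signal map with one planted 3'-end coverage drop-out.

    UTRs are laid end to end with gaps; all bases carry Gaussian noise and
    the trailing ``dropout_fraction`` of the chosen UTR is shifted by
    ``amplitude`` (the treatment-minus-control coverage drop).  Returns the
    map, the UTR interval list and the global change-point position.
    """
    rng = np.random.default_rng(seed)
    total = n_utrs * (utr_length + gap) + gap
    values = rng.normal(0.0, noise_sd, size=total)
    utrs = []
    cp_global = -1
    for i in range(n_utrs):
        start = gap + i * (utr_length + gap)
        end = start + utr_length
        utrs.append((f"utr{i + 1:02d}", chrom, start, end))
        if i == dropout_utr:
            cp_local = int(round(utr_length * (1.0 - dropout_fraction)))
            cp_global = start + cp_local
            values[cp_global:end] += amplitude
    track = CoverageTrack(chrom, 0, values)
    return {chrom: track}, utrs, cp_global
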