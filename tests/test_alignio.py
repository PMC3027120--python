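import random

import numpy as np
import pysam
import pytest

from genesig.alignio import (
    AlignmentInputError,
    cigar_reference_blocks,
    is_unique,
    load_exon_alignments,
    load_junction_reads,
    merge_alignment_files,
    sort_alignment_file,
)

HEADER = ["@HD\tVN:1.6", "@SQ\tSN:chr1\tLN:10000", "@SQ\tSN:chr2\tLN:10000"]


def sam_record(qname, chrom, pos0, mapq=60, cigar="10M", flag=0, nh=None):
    if flag & 4:
        return f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\t*\t*"
    tag = f"\tNH:i:{nh}" if nh is not None else ""
    return f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}\t*\t0\t0\t{'A' * 10}\t*{tag}"


def write_sam(path, records, header=HEADER):
    path.write_text("\n".join(header + records) + "\n")
    return path


class TestUniqueness:
    @pytest.mark.parametrize(
        "mapq, nh, expected",
        [
            (0, 1, True),  # NH takes precedence over MAPQ
            (60, 3, False),
            (37, None, True),
            (0, None, False),
        ],
    )
    def test_rule(self, mapq, nh, expected):
        assert is_unique(mapq, nh) is expected


class TestLoadExonAlignments:
    def test_unmapped_counted_in_total_only(self, tmp_path):
        recs = [
            sam_record("r1", "chr1", 50),
            sam_record("r2", "chr1", 10),
            sam_record("r3", "chr1", 30),
            sam_record("r4", None, 0, flag=4),
        ]
        sample = load_exon_alignments(write_sam(tmp_path / "a.sam", recs))
        assert sample.n_total_records == 4
        assert sample.n_unique == 3
        assert [r.start for r in sample.reads_by_chrom["chr1"]] == [10, 30, 50]

    def test_multimapped_excluded(self, tmp_path):
        recs = [sam_record(f"r{i}", "chr1", i * 10, nh=(2 if i < 200 else 1)) for i in range(1000)]
        sample = load_exon_alignments(write_sam(tmp_path / "b.sam", recs))
        # brute-force flag scan oracle
        expected = sum(1 for i in range(1000) if not i < 200)
        assert sample.n_unique == expected == 800
        assert sample.n_total_records == 1000

    def test_empty_file_is_valid(self, tmp_path):
        sample = load_exon_alignments(write_sam(tmp_path / "c.sam", []))
        assert sample.n_total_records == 0 and sample.n_unique == 0

    def test_header_sizes_captured(self, tmp_path):
        sample = load_exon_alignments(write_sam(tmp_path / "d.sam", []))
        assert sample.chrom_sizes == {"chr1": 10000, "chr2": 10000}

    def test_n_unique_invariant_under_record_order(self, tmp_path):
        rng = random.Random(7)
        recs = [
            sam_record(f"r{i}", rng.choice(["chr1", "chr2"]), rng.randrange(5000),
                       nh=rng.choice([1, 1, 1, 2]))
            for i in range(300)
        ]
        base = load_exon_alignments(write_sam(tmp_path / "e1.sam", recs))
        rng.shuffle(recs)
        shuffled = load_exon_alignments(write_sam(tmp_path / "e2.sam", recs))
        assert base.n_unique == shuffled.n_unique
        for chrom in base.reads_by_chrom:
            assert [r.start for r in base.reads_by_chrom[chrom]] == [
                r.start for r in shuffled.reads_by_chrom[chrom]
            ]


class TestCigarBlocks:
    @pytest.mark.parametrize(
        "cigar, start, blocks",
        [
            ("5M", 10, [(10, 15)]),
            ("3M4N3M", 10, [(10, 13), (17, 20)]),
            ("2M1D2M", 0, [(0, 2), (3, 5)]),  # deletion not covered
            ("3S5M2I4M", 100, [(100, 109)]),  # soft clip / insertion consume no ref
        ],
    )
    def test_reference_blocks(self, cigar, start, blocks):
        assert cigar_reference_blocks(cigar, start) == blocks


class TestJunctionBed:
    def test_bed12_two_blocks(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("chr1\t90\t410\tJUNC1\t5\t+\t90\t410\t0\t2\t20,20\t0,300\n")
        (j,) = load_junction_reads(p)
        assert (j.left_block.start, j.left_block.end) == (90, 110)
        assert (j.right_block.start, j.right_block.end) == (390, 410)
        assert j.count == 5

    def test_count_mode_one(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("chr1\t90\t410\tJUNC1\t5\t+\t90\t410\t0\t2\t20,20\t0,300\n")
        (j,) = load_junction_reads(p, count_mode="one")
        assert j.count == 1

    def test_bed6_rejected_unless_configured(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("chr1\t100\t400\tj\t1\t+\n")
        with pytest.raises(AlignmentInputError, match="line 1"):
            load_junction_reads(p)
        (j,) = load_junction_reads(p, allow_bed6=True)
        assert (j.left_block.start, j.left_block.end) == (100, 101)
        assert (j.right_block.start, j.right_block.end) == (399, 400)
        assert j.count == 1

    def test_wrong_block_count_names_line(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("chr1\t0\t300\tj\t1\t+\t0\t300\t0\t3\t10,10,10\t0,100,290\n")
        with pytest.raises(AlignmentInputError, match="line 1"):
            load_junction_reads(p)

    def test_empty_file(self, tmp_path):
        p = tmp_path / "j.bed"
        p.write_text("")
        assert load_junction_reads(p) == []


def _record_keys(path):
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        return [(r.reference_id, r.reference_start, r.query_name) for r in fh]


class TestSortMerge:
    def test_sort_is_idempotent(self, tmp_path):
        recs = [sam_record(f"r{i}", "chr1", i * 5) for i in range(10)]
        p = write_sam(tmp_path / "s.sam", recs)
        out1, out2 = tmp_path / "s1.sam", tmp_path / "s2.sam"
        sort_alignment_file(p, out1)
        sort_alignment_file(out1, out2)
        assert _record_keys(out1) == _record_keys(out2)

    def test_sort_matches_oracle_and_is_stable(self, tmp_path):
        rng = random.Random(3)
        recs = [
            sam_record(f"r{i}", rng.choice(["chr1", "chr2"]), rng.randrange(50), cigar="10M")
            for i in range(500)
        ]
        p = write_sam(tmp_path / "big.sam", recs)
        out = tmp_path / "big.sorted.sam"
        sort_alignment_file(p, out)
        # oracle: full sort of (chrom_index, start, input_index) triples
        chrom_index = {"chr1": 0, "chr2": 1}
        parsed = []
        for i, rec in enumerate(recs):
            f = rec.split("\t")
            parsed.append((chrom_index[f[2]], int(f[3]) - 1, i, f[0]))
        expected = [name for *_key, name in sorted(parsed)]
        assert [name for *_k, name in _record_keys(out)] == expected

    def test_merge_two_sorted_files(self, tmp_path):
        a = write_sam(tmp_path / "a.sam", [sam_record(f"a{i}", "chr1", i * 10) for i in range(3)])
        b = write_sam(tmp_path / "b.sam", [sam_record(f"b{i}", "chr1", i * 10 + 5) for i in range(3)])
        out = tmp_path / "m.sam"
        merge_alignment_files([a, b], out)
        keys = _record_keys(out)
        assert [k[1] for k in keys] == [0, 5, 10, 15, 20, 25]

    def test_merge_stable_for_equal_keys(self, tmp_path):
        a = write_sam(tmp_path / "a.sam", [sam_record("a0", "chr1", 100)])
        b = write_sam(tmp_path / "b.sam", [sam_record("b0", "chr1", 100)])
        out = tmp_path / "m.sam"
        merge_alignment_files([a, b], out)
        assert [k[2] for k in _record_keys(out)] == ["a0", "b0"]

    def test_merge_rejects_incompatible_headers(self, tmp_path):
        a = write_sam(tmp_path / "a.sam", [])
        b = write_sam(
            tmp_path / "b.sam", [], header=["@HD\tVN:1.6", "@SQ\tSN:chrX\tLN:5000"]
        )
        with pytest.raises(AlignmentInputError, match="incompatible"):
            merge_alignment_files([a, b], tmp_path / "m.sam")

    def test_load_of_sorted_equals_load_of_unsorted(self, tmp_path):
        rng = random.Random(9)
        recs = [sam_record(f"r{i}", "chr1", rng.randrange(1000)) for i in range(100)]
        p = write_sam(tmp_path / "u.sam", recs)
        out = tmp_path / "u.sorted.sam"
        sort_alignment_file(p, out)
        s1, s2 = load_exon_alignments(p), load_exon_alignments(out)
        assert s1.n_unique == s2.n_unique
        assert np.array_equal(s1.starts("chr1"), s2.starts("chr1"))
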