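import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from genesig import (
    AlignedRead,
    AnnotationIndex,
    ExonInterval,
    GeneModel,
    JunctionRead,
    SampleAlignment,
)
from genesig.expression import (
    count_exon_reads,
    count_junction_reads,
    expression_matrix,
    expression_records,
    fold_change,
    rpkm,
)


def make_sample(starts_by_chrom, sample_id="s"):
    sample = SampleAlignment(sample_id=sample_id)
    for chrom, starts in starts_by_chrom.items():
        for pos in starts:
            sample.add(AlignedRead(chrom, pos, "10M", 60, 0, True))
    return sample.finalize()


GENE = GeneModel("g", "chr1", "+", [ExonInterval("chr1", 100, 200), ExonInterval("chr1", 400, 500)])


class TestRpkm:
    @pytest.mark.parametrize(
        "c_a, c_b, n, length, expected",
        [
            (100, 0, 10**6, 1000, 100.0),
            (0, 0, 10**6, 1000, 0.0),
            (50, 50, 2 * 10**6, 500, 100.0),
        ],
    )
    def test_direct_substitution(self, c_a, c_b, n, length, expected):
        assert rpkm(c_a, c_b, n, length) == pytest.approx(expected)

    @pytest.mark.parametrize("n, length", [(0, 1000), (10**6, 0)])
    def test_undefined_score_rejected(self, n, length):
        with pytest.raises(ValueError):
            rpkm(1, 0, n, length)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        c_a=st.integers(0, 10**5),
        c_b=st.integers(0, 10**5),
        n=st.integers(1, 10**8),
        length=st.integers(1, 10**6),
    )
    def test_scale_symmetry_linearity(self, c_a, c_b, n, length):
        base = rpkm(c_a, c_b, n, length)
        # doubling all counts and N leaves the score unchanged
        assert rpkm(2 * c_a, 2 * c_b, 2 * n, length) == pytest.approx(base)
        # c_exon and c_junction are exchangeable
        assert rpkm(c_b, c_a, n, length) == pytest.approx(base)
        # linear in the summed count
        assert rpkm(3 * c_a, 3 * c_b, n, length) == pytest.approx(3 * base)


class TestCountExonReads:
    def test_half_open_exon_end(self):
        gene = GeneModel("g", "chr1", "+", [ExonInterval("chr1", 100, 200)])
        sample = make_sample({"chr1": [150, 199, 200]})
        assert count_exon_reads(sample, gene) == 2

    def test_no_reads_on_gene_chromosome(self):
        assert count_exon_reads(make_sample({"chr2": [150]}), GENE) == 0

    def test_matches_naive_membership_scan(self):
        rng = np.random.default_rng(42)
        genes = []
        pos = 0
        for i in range(20):
            exons = []
            start = pos + int(rng.integers(50, 200))
            for _ in range(int(rng.integers(1, 4))):
                end = start + int(rng.integers(30, 150))
                exons.append(ExonInterval("chr1", start, end))
                start = end + int(rng.integers(20, 100))
            genes.append(GeneModel(f"g{i}", "chr1", "+", exons))
            pos = start
        sample = make_sample({"chr1": sorted(rng.integers(0, pos + 500, size=2000).tolist())})
        for gene in genes:
            naive = sum(
                1
                for r in sample.reads_by_chrom["chr1"]
                if any(e.start <= r.start < e.end for e in gene.exons)
            )
            assert count_exon_reads(sample, gene) == naive


class TestCountJunctionReads:
    def test_both_anchors_on_exons(self):
        j = JunctionRead("chr1", ExonInterval("chr1", 90, 110), ExonInterval("chr1", 390, 410), 5)
        assert count_junction_reads([j], GENE) == 5

    def test_one_anchor_intergenic(self):
        j = JunctionRead("chr1", ExonInterval("chr1", 150, 170), ExonInterval("chr1", 900, 920), 3)
        assert count_junction_reads([j], GENE) == 0

    def test_wrong_chromosome(self):
        j = JunctionRead("chr2", ExonInterval("chr2", 150, 170), ExonInterval("chr2", 420, 440), 2)
        assert count_junction_reads([j], GENE) == 0

    def test_matches_naive_double_loop(self):
        rng = np.random.default_rng(17)
        genes = [
            GeneModel(
                f"g{i}",
                "chr1",
                "+",
                [
                    ExonInterval("chr1", 1000 * i + 100, 1000 * i + 300),
                    ExonInterval("chr1", 1000 * i + 500, 1000 * i + 700),
                ],
            )
            for i in range(5)
        ]
        junctions = []
        for _ in range(200):
            a = int(rng.integers(0, 4500))
            b = a + 20 + int(rng.integers(0, 400))
            junctions.append(
                JunctionRead(
                    "chr1",
                    ExonInterval("chr1", a, a + 15),
                    ExonInterval("chr1", b, b + 15),
                    int(rng.integers(1, 5)),
                )
            )
        for gene in genes:
            naive = sum(
                j.count
                for j in junctions
                if any(e.overlaps(j.left_block.start, j.left_block.end) for e in gene.exons)
                and any(e.overlaps(j.right_block.start, j.right_block.end) for e in gene.exons)
            )
            assert count_junction_reads(junctions, gene) == naive


class TestExpressionMatrix:
    def test_identical_samples_give_equal_columns(self):
        index = AnnotationIndex.from_genes([GENE])
        s1 = make_sample({"chr1": [110, 120, 450]}, "a")
        s2 = make_sample({"chr1": [110, 120, 450]}, "b")
        m = expression_matrix([(s1, []), (s2, [])], index)
        assert (m["a"] == m["b"]).all()

    def test_gene_absent_from_sample_chromosomes_scores_zero(self):
        index = AnnotationIndex.from_genes([GENE])
        m = expression_matrix([(make_sample({"chr2": [10, 20]}, "a"), [])], index)
        assert m.loc["g", "a"] == 0.0

    def test_duplicate_sample_ids_rejected(self):
        index = AnnotationIndex.from_genes([GENE])
        s = make_sample({"chr1": [110]}, "a")
        with pytest.raises(ValueError, match="duplicate"):
            expression_matrix([(s, []), (s, [])], index)

    def test_n_includes_junction_support(self):
        index = AnnotationIndex.from_genes([GENE])
        sample = make_sample({"chr1": [110]}, "a")
        j = JunctionRead("chr1", ExonInterval("chr1", 190, 200), ExonInterval("chr1", 400, 410), 3)
        recs = expression_records(sample, [j], index)
        assert recs[0].n_mapped == 1 + 3
        assert recs[0].c_exon == 1 and recs[0].c_junction == 3
        assert recs[0].rpkm == pytest.approx(1e9 * 4 / (4 * 200))

    def test_custom_interval_mode_reproduces_gene_mode(self):
        # treating each gene's exons as user-defined intervals gives the same matrix
        index = AnnotationIndex.from_genes([GENE])
        custom = AnnotationIndex.from_genes(
            [GeneModel("g", "chr1", "+", [ExonInterval("chr1", e.start, e.end) for e in GENE.exons])]
        )
        sample = make_sample({"chr1": [110, 450, 499]}, "a")
        m1 = expression_matrix([(sample, [])], index)
        m2 = expression_matrix([(sample, [])], custom)
        assert m1.equals(m2)


class TestFoldChange:
    def test_simple_ratio_and_neutral_zero_gene(self):
        index = AnnotationIndex.from_genes([GENE])
        s1 = make_sample({"chr1": [110] * 2}, "t")
        s2 = make_sample({"chr1": [110]}, "c")
        m = expression_matrix([(s1, []), (s2, [])], index)
        fc = fold_change(m, ["t"], ["c"], pseudocount=0.0)
        assert fc["g"] == pytest.approx(m.loc["g", "t"] / m.loc["g", "c"])

    def test_all_zero_gene_with_pseudocount_is_neutral(self):
        index = AnnotationIndex.from_genes([GENE])
        s1 = make_sample({"chr2": [10]}, "t")
        s2 = make_sample({"chr2": [20]}, "c")
        m = expression_matrix([(s1, []), (s2, [])], index)
        assert fold_change(m, ["t"], ["c"]).loc["g"] == pytest.approx(1.0)

    def test_matches_direct_arithmetic(self):
        import pandas as pd

        rng = np.random.default_rng(1)
        m = pd.DataFrame(
            rng.uniform(0, 100, size=(10, 4)),
            index=[f"g{i}" for i in range(10)],
            columns=["t1", "t2", "c1", "c2"],
        )
        fc = fold_change(m, ["t1", "t2"], ["c1", "c2"], pseudocount=0.5)
        expected = (m[["t1", "t2"]].to_numpy().mean(axis=1) + 0.5) / (
            m[["c1", "c2"]].to_numpy().mean(axis=1) + 0.5
        )
        assert np.allclose(fc.to_numpy(), expected)

    @pytest.mark.parametrize(
        "t_cols, c_cols, err",
        [(["t1"], ["t1"], ValueError), ([], ["c1"], ValueError), (["nope"], ["c1"], KeyError)],
    )
    def test_bad_column_sets_rejected(self, t_cols, c_cols, err):
        import pandas as pd

        m = pd.DataFrame({"t1": [1.0], "c1": [2.0]}, index=["g"])
        with pytest.raises(err):
            fold_change(m, t_cols, c_cols)
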