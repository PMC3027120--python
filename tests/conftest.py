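import pytest

from genesig import (
    AnnotationIndex,
    ExonInterval,
    GeneModel,
    SimulationConfig,
    generate_synthetic_dataset,
)


@pytest.fixture(scope="session")
def toy_index() -> AnnotationIndex:
    """Two genes on chr1 (one pair overlapping) and one on chr2."""
    return AnnotationIndex.from_genes(
        [
            GeneModel(
                "geneA",
                "chr1",
                "+",
                [ExonInterval("chr1", 100, 200), ExonInterval("chr1", 400, 500)],
            ),
            GeneModel(
                "geneB",
                "chr1",
                "-",
                [ExonInterval("chr1", 450, 600), ExonInterval("chr1", 700, 800)],
            ),
            GeneModel("geneC", "chr2", "+", [ExonInterval("chr2", 50, 250)]),
        ]
    )


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory):
    """A generated two-sample dataset shared by file-level tests."""
    out = tmp_path_factory.mktemp("small_ds")
    config = SimulationConfig(seed=11, n_reads=2_000, n_samples=2, n_genes=10)
    return generate_synthetic_dataset(config, out)
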