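import numpy as np
import pytest

from nephroscope import simulate
from nephroscope.io import CountMatrix, ExpressionMatrix, GeneListRegistry


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 4 cells with hand-checkable totals."""
    counts = np.array([
        [5, 0, 2, 1],
        [0, 3, 0, 0],
        [1, 1, 4, 0],
    ])
    return CountMatrix(["MT-CO1", "ACTB", "GAPDH"], ["c1", "c2", "c3", "c4"], counts)


@pytest.fixture
def registry() -> GeneListRegistry:
    return simulate.default_registry()


@pytest.fixture(scope="session")
def clustered_data():
    """A small clustered simulation shared by several test modules."""
    spec = simulate.CountSimSpec(n_clusters=5, cells_per_cluster=80, n_genes=800,
                                 marker_fold=8.0, seed=7)
    return simulate.generate_counts(spec)


def expression_from_counts(cm: CountMatrix, tag: str = "raw") -> ExpressionMatrix:
    return ExpressionMatrix(list(cm.genes), list(cm.cells), cm.counts.astype(float), tag)
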