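import numpy as np
import pytest

from basin import (
    ExpressionMatrix,
    SingleCellReference,
    SpotGeometry,
    build_graph,
    identity_graph,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def tiny_st():
    """3 genes × 2 spots with simple integer counts."""
    return ExpressionMatrix(
        values=np.array([[1.0, 2.0], [0.0, 3.0], [4.0, 0.0]]),
        gene_ids=["g1", "g2", "g3"],
        spot_ids=["s1", "s2"],
    )


@pytest.fixture
def tiny_sc():
    """4 genes × 4 cells over two types."""
    return SingleCellReference(
        values=np.array(
            [
                [2.0, 4.0, 1.0, 1.0],
                [0.0, 0.0, 5.0, 7.0],
                [1.0, 1.0, 1.0, 1.0],
                [3.0, 5.0, 0.0, 2.0],
            ]
        ),
        gene_ids=["g1", "g2", "g3", "g4"],
        cell_ids=["c1", "c2", "c3", "c4"],
        cell_type_labels=["A", "A", "B", "B"],
    )


@pytest.fixture(scope="session")
def small_synthetic():
    """Scheme-1 dataset on a 10 × 10 grid, shared across read-only tests."""
    return simulate_dataset(
        scheme=1, grid_shape=(10, 10), n_genes=80, separation=2.0, seed=7
    )


@pytest.fixture
def line_geometry():
    """Five spots on a line, unit spacing."""
    return SpotGeometry(coords=np.column_stack([np.arange(5.0), np.zeros(5)]))
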