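import numpy as np
import pytest

from mcimpute import CellLabels, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_counts():
    """4 cells x 6 genes count matrix exercising the filtering rule.

    Gene columns are designed so that exactly genes g0, g2 and g5 have
    >= 3 reads in at least 3 cells.
    """
    values = np.array(
        [
            # g0  g1  g2  g3  g4  g5
            [3,   2,  5,  0,  0, 10],
            [4,   5,  3,  2,  0,  7],
            [3,   0,  9,  1,  0,  4],
            [0,   0,  3,  0,  0,  6],
        ],
        dtype=float,
    )
    return ExpressionMatrix(
        values,
        cell_ids=[f"c{i}" for i in range(4)],
        gene_ids=[f"g{j}" for j in range(6)],
        layer="counts",
    )


@pytest.fixture
def two_group_labels():
    return CellLabels(["NP", "NP", "TH", "TH"], ["c0", "c1", "c2", "c3"])
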