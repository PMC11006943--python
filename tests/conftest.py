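import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from mztkin import synth
from mztkin.datatypes import CellTable, SynthConfig


@pytest.fixture(scope="session")
def small_table() -> CellTable:
    """A 50-gene, 400-cell synthetic table with a mixed truth panel."""
    truths = synth.default_truth_panel(50, rng_seed=11)
    return synth.simulate_cell_table(truths, SynthConfig(n_genes=50, n_cells=400, seed=11))


@pytest.fixture(scope="session")
def small_truths():
    return synth.default_truth_panel(50, rng_seed=11)


@pytest.fixture()
def toy_table() -> CellTable:
    """Tiny hand-checkable table: 3 genes x 4 cells."""
    counts = np.array([
        [10, 0, 3, 2],
        [0, 5, 40, 1],
        [90, 95, 7, 7],
    ])
    ntr = np.array([
        [0.3, np.nan, 0.0, 1.0],
        [np.nan, 0.5, 0.9, np.nan],
        [0.1, 0.2, np.nan, 0.5],
    ])
    meta = pd.DataFrame({
        "stage": ["dome", "dome", "epb30", "epb30"],
        "cluster": ["a", "a", "b", "b"],
        "pseudotime_au": [0.2, 0.4, 0.6, 0.8],
        "replicate": ["A", "B", "A", "B"],
    }, index=[f"c{i}" for i in range(4)])
    return CellTable(genes=pd.Index(["g0", "g1", "g2"]),
                     counts=sparse.csr_matrix(counts), ntr=ntr, meta=meta)
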