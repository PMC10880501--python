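import numpy as np
import pandas as pd
import pytest

from sctriage import CountMatrix, SimulationConfig
from sctriage.qc import normalize
from sctriage.simulate import gen_counts


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=1)


@pytest.fixture(scope="session")
def default_data(default_config):
    """One default synthetic dataset shared across read-only tests."""
    cm, truth = gen_counts(default_config)
    return cm, truth


@pytest.fixture(scope="session")
def default_normalized(default_data):
    cm, truth = default_data
    return normalize(cm), truth


def make_count_matrix(counts, groups=None, genes=None):
    """Small hand-built CountMatrix helper."""
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    cells = [f"C{i}" for i in range(n_cells)]
    groups = groups or ["tumor"] * (n_cells // 2) + ["normal"] * (n_cells - n_cells // 2)
    meta = pd.DataFrame(
        {"sample": ["S1"] * n_cells, "group": groups},
        index=pd.Index(cells, name="barcode"),
    )
    return CountMatrix(genes=genes, cells=cells, counts=counts, cell_meta=meta)
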