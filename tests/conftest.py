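import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from statekit.core_io import AnalysisConfig, CountMatrix
from statekit.synthetic_data import StateSpec, simulate_expression


@pytest.fixture(scope="session")
def sim_config():
    """Pipeline thresholds rescaled to the simulator's ~560-gene panel
    (the real-data gene floor of 1500 cannot be met on a small panel)."""
    return AnalysisConfig().replace(min_genes_hsc=200, min_genes_mpp=250)


@pytest.fixture(scope="session")
def separable_sim():
    """Well-separated 3-state simulation shared by clustering tests."""
    spec = StateSpec.separable()
    counts, cells, truth = simulate_expression(spec, 600, seed=11)
    return spec, counts, cells, truth


@pytest.fixture(scope="session")
def default_sim():
    """The full study-conditions simulation (5 conditions, batches, sexes,
    doublets)."""
    spec = StateSpec.default()
    counts, cells, truth = simulate_expression(spec, 900, seed=7)
    return spec, counts, cells, truth


def toy_counts(dense, barcodes=None, features=None, modality="gene",
               **feat_cols):
    dense = np.asarray(dense)
    n, m = dense.shape
    barcodes = barcodes or [f"bc{i}" for i in range(n)]
    features = features or [f"f{j}" for j in range(m)]
    feat = pd.DataFrame(feat_cols, index=pd.Index(features))
    return CountMatrix(sp.csr_matrix(dense), pd.Index(barcodes), feat,
                       modality)


@pytest.fixture
def toy_counts_factory():
    return toy_counts
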