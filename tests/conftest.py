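import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import ulmnet as u


@pytest.fixture(scope="session")
def default_sim():
    """The default synthetic benchmark (seed 1), drawn once per session."""
    cfg = u.SimulationConfig()
    matrix, truth = u.simulate_cells(cfg)
    return cfg, matrix, truth


@pytest.fixture(scope="session")
def default_fit(default_sim):
    """Full pipeline fit on the default benchmark."""
    _, matrix, truth = default_sim
    model = u.UlmNet(matrix, annotations=u.singlet_annotations(truth))
    with pytest.warns(UserWarning):  # signature sets smaller than top_n
        return model.fit()


@pytest.fixture(scope="session")
def small_sim():
    """A reduced benchmark for fast structural tests."""
    cfg = u.SimulationConfig(
        n_genes=400, n_types=3, markers_per_type=25, n_singlets_per_type=60,
        multiplet_spec=[("A_B", 25), ("B_C", 25), ("A_B_C", 12)], seed=7,
    )
    matrix, truth = u.simulate_cells(cfg)
    return cfg, matrix, truth


def random_matrix(rng, n_genes=50, n_cells=20, density=0.3, max_count=40):
    """Random sparse integer count matrix with labelled axes."""
    counts = sp.random(n_genes, n_cells, density=density, random_state=rng,
                       data_rvs=lambda k: rng.integers(1, max_count, k))
    counts = sp.csr_matrix(counts, dtype=np.int64)
    genes = [f"gene{i}" for i in range(n_genes)]
    cells = [f"cell{j}" for j in range(n_cells)]
    return u.ExpressionMatrix(counts, genes, cells)


def toy_scores(t, p, barcodes=None, signatures=None, df=100):
    t = np.atleast_2d(np.asarray(t, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    barcodes = barcodes or [f"bc{i}" for i in range(t.shape[0])]
    signatures = signatures or [f"S{j}" for j in range(t.shape[1])]
    return u.ActivityScoreMatrix(barcodes=barcodes, signatures=signatures,
                                 t_value=t, p_value=p, df=df, genes_used=df + 2)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def truth_labels():
    def _labels(truth: pd.DataFrame) -> pd.Series:
        return truth.set_index("barcode")["category"].map(
            lambda c: "singlet" if c == "singlet" else "doublet")
    return _labels
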