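import numpy as np
import pytest

from scipac import SCIPAC
from scipac.simulate import simulate_discrete_scheme


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small three-type discrete dataset, cheap enough for many tests."""
    return simulate_discrete_scheme(
        3, (1, -1, 0), m_cells=240, n_bulk=80, p_genes=90, seed=7,
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_dataset):
    """Full pipeline on the tiny dataset, clustering bypassed by the true
    cell types (keeps the run fast and the cluster structure known)."""
    ds = tiny_dataset
    model = SCIPAC(ds.sc, ds.bulk, ds.pheno, cell_labels=ds.cell_types)
    res = model.fit(bootstrap_reps=20, seed=7)
    return ds, res


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
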