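import numpy as np
import pandas as pd
import pytest

from idicss.ica import fit_ica
from idicss.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One desk-scale cohort with planted structure, shared across tests."""
    return simulate_cohort(SimConfig(seed=11))


@pytest.fixture(scope="session")
def default_decomposition(default_cohort):
    bundle, _ = default_cohort
    return fit_ica(bundle.expression, 10, seed=11)


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort for fast smoke tests of the full pipeline."""
    config = SimConfig(
        n_genes=600,
        n_samples=150,
        n_components=6,
        n_immune_components=2,
        immune_set_size=40,
        n_drivers=10,
        n_risk_genes=6,
        seed=21,
    )
    return simulate_cohort(config)


@pytest.fixture()
def toy_expression(tmp_path):
    path = tmp_path / "expr.tsv"
    df = pd.DataFrame(
        [[1.0, 2.0], [3.5, 4.25], [5.0, 6.0]],
        index=["GA", "GB", "GC"],
        columns=["s1", "s2"],
    )
    df.to_csv(path, sep="\t", index_label="gene")
    return path, df


def make_decomposition(loadings: np.ndarray, genes=None, samples=None):
    """Build an ICADecomposition directly from a loading matrix (for tests
    of operations that only consume S)."""
    from idicss.ica import ICADecomposition

    n_genes, k = loadings.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    ids = [f"IC{i + 1}" for i in range(k)]
    samples = samples or ["sA", "sB"]
    W = np.zeros((k, len(samples)))
    return ICADecomposition(
        S=pd.DataFrame(loadings, index=genes, columns=ids),
        W=pd.DataFrame(W, index=ids, columns=samples),
        k=k,
        seed=0,
        n_iter=1,
        converged=True,
    )
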