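import numpy as np
import pytest
import scipy.sparse as sp

from sgcpi.embedding import SkipgramConfig
from sgcpi.models import TrainConfig
from sgcpi.pipeline import RunConfig
from sgcpi.synthetic import SynthConfig


def random_symmetric_adjacency(rng: np.random.Generator, n: int,
                               p: float = 0.4) -> sp.csr_matrix:
    """Random undirected graph with zero diagonal, for oracle comparisons."""
    A = (rng.random((n, n)) < p).astype(float)
    A = np.triu(A, 1)
    A = A + A.T
    return sp.csr_matrix(A)


@pytest.fixture(scope="session")
def tiny_run_config() -> RunConfig:
    """Small but non-trivial end-to-end configuration (fast: ~seconds)."""
    return RunConfig(
        synth=SynthConfig(n_compounds=45, n_proteins=12, seed=11,
                          seq_length_range=(60, 90)),
        embed=SkipgramConfig(d=24, epochs=4, window=3, seed=0),
        train=TrainConfig(epochs=60, patience=None),
        knn=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_ablation_config() -> RunConfig:
    """Mid-size fixture for the imbalance / corpus ablation properties."""
    return RunConfig(
        synth=SynthConfig(n_compounds=60, n_proteins=18, seed=5,
                          seq_length_range=(60, 100)),
        embed=SkipgramConfig(d=32, epochs=6, window=4, seed=0),
        train=TrainConfig(epochs=80, patience=None),
        knn=8,
        seed=5,
    )
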