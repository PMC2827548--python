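import numpy as np
import pytest

from gkonp.dds_model import DDSModel
from gkonp.synthetic_data import EnsembleSpec, random_sparse_dds, toy_fixtures


@pytest.fixture
def two_gene_inhibitor() -> DDSModel:
    """Two genes, the first repressing the second (the target)."""
    return toy_fixtures()["two_gene_inhibitor"]["model"]


@pytest.fixture
def feedforward_pair() -> DDSModel:
    """Gene 1 feeds gene 2 (the target) positively; both persist."""
    return DDSModel(
        gene_names=["g1", "g2"],
        M=np.array([[1.0, 0.0], [1.0, 1.0]]),
        x0=np.array([1.0, 0.0]),
        horizon=2,
        target=1,
    )


@pytest.fixture
def toys() -> dict:
    return toy_fixtures()


def small_random_models(n_genes: int, n_models: int, seed: int, horizon: int = 8):
    """Seeded sparse ensemble used across property tests."""
    spec = EnsembleSpec(
        n_genes=n_genes, max_parents=2, horizon=horizon, seed=seed, n_models=n_models
    )
    return random_sparse_dds(spec)


def random_knockouts(n: int, target: int, count: int, rng: np.random.Generator):
    """Random binary knockout matrix with the target column forced intact."""
    S = (rng.random((count, n)) < 0.5).astype(float)
    S[:, target] = 1.0
    return S
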