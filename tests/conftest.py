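import numpy as np
import pytest

from cspnet import PathwayCollection, PPINetwork


@pytest.fixture
def tiny_ppi() -> PPINetwork:
    """Path graph g1-g2-g3 plus an isolated interaction g4-g5."""
    return PPINetwork([("g1", "g2"), ("g2", "g3"), ("g4", "g5")])


@pytest.fixture
def shared_gene_instance():
    """The canonical shared-gene counting instance: g2 belongs to both sets."""
    ppi = PPINetwork([("g1", "g2"), ("g2", "g3")])
    return ppi, {"g1", "g2"}, {"g2", "g3"}


@pytest.fixture
def small_collection() -> PathwayCollection:
    return PathwayCollection(
        {"A": {"g1", "g2"}, "B": {"g2", "g3"}, "C": {"g4", "g5"}}
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_ppi(rng: np.random.Generator, n_genes: int, density: float) -> PPINetwork:
    genes = [f"g{i}" for i in range(n_genes)]
    iu, ju = np.triu_indices(n_genes, 1)
    mask = rng.random(iu.size) < density
    return PPINetwork([(genes[i], genes[j]) for i, j in zip(iu[mask], ju[mask])])
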