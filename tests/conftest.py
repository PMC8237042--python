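import numpy as np
import pytest

from netdistancing import Graph


@pytest.fixture
def path4():
    """Path graph a-b-c-d: the classic enumerable MCMC toy instance."""
    return Graph.from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture
def k4():
    return Graph.from_edges(4, [(i, j) for i in range(4) for j in range(i + 1, 4)])


@pytest.fixture
def star4():
    """Star with 4 leaves (K_{1,4})."""
    return Graph.from_edges(5, [(0, i) for i in range(1, 5)])


def random_graph(n: int, p: float, seed: int) -> Graph:
    rng = np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    hit = rng.random(len(iu)) < p
    return Graph.from_edges(n, zip(iu[hit].tolist(), ju[hit].tolist()))
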