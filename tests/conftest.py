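import numpy as np
import pytest

from regdom.graph_model import RegulatoryNetwork


@pytest.fixture
def out_star() -> RegulatoryNetwork:
    """center regulates l1..l5; MDS = MCDS = {center}."""
    return RegulatoryNetwork.from_arcs([("center", f"l{i}") for i in range(1, 6)])


@pytest.fixture
def path3() -> RegulatoryNetwork:
    return RegulatoryNetwork.from_arcs([("a", "b"), ("b", "c")])


@pytest.fixture
def cycle3() -> RegulatoryNetwork:
    return RegulatoryNetwork.from_arcs([("a", "b"), ("b", "c"), ("c", "a")])


@pytest.fixture
def two_regulator_net() -> RegulatoryNetwork:
    """Two regulators A, B jointly covering C, E, D with C linking them."""
    return RegulatoryNetwork.from_arcs(
        [("A", "C"), ("A", "E"), ("B", "C"), ("B", "D"), ("C", "B")]
    )


@pytest.fixture
def two_wcc_net() -> RegulatoryNetwork:
    """A dense 3-cycle + pendant in one WCC, a separate 2-node WCC."""
    return RegulatoryNetwork.from_arcs(
        [("a", "b"), ("b", "c"), ("c", "a"), ("a", "d"), ("e", "f")]
    )


def random_digraph(n: int, p: float, seed: int) -> RegulatoryNetwork:
    """Seeded Erdős–Rényi digraph built independently of regdom.synthetic."""
    rng = np.random.default_rng(seed)
    names = [f"v{i}" for i in range(n)]
    arcs = [
        (names[i], names[j])
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return RegulatoryNetwork.from_arcs(arcs, nodes=names)
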