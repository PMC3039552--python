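import numpy as np
import pytest

from arealrisk import AreaGraph, IncidenceDataset


@pytest.fixture(scope="session")
def path3_graph() -> AreaGraph:
    """Three areas in a path a-b-c with unit-spaced centroids."""
    return AreaGraph(
        ("a", "b", "c"),
        (frozenset({1}), frozenset({0, 2}), frozenset({1})),
        np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]]),
    )


@pytest.fixture(scope="session")
def path3_data() -> IncidenceDataset:
    return IncidenceDataset(("a", "b", "c"), np.array([2, 5, 9]), np.array([4.0, 5.0, 6.0]))


@pytest.fixture(scope="session")
def lattice10():
    """10x10 queen lattice (no islands)."""
    from arealrisk.simulate import make_geography

    _, graph = make_geography(10, 10, 0, seed=0)
    return graph
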