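import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module


@pytest.fixture
def path5() -> nx.Graph:
    """The path 1-2-3-4-5 with string labels."""
    g = nx.Graph()
    nx.add_path(g, ["1", "2", "3", "4", "5"])
    return g


@pytest.fixture
def cycle6() -> nx.Graph:
    """The 6-cycle with string labels 1..6."""
    g = nx.cycle_graph(6)
    return nx.relabel_nodes(g, {i: str(i + 1) for i in range(6)})


@pytest.fixture
def triangle() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c")])
    return g


@pytest.fixture(scope="session")
def small_ba() -> nx.Graph:
    """A 300-node preferential-attachment graph for mid-size tests."""
    from netsep import generate_interactome

    return generate_interactome(300, 2, seed=7)
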