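import random

import networkx as nx
import pytest

from herbnet.screen import CompoundRecord


@pytest.fixture
def passing_record():
    """A compound that clears both ADME screens."""
    return CompoundRecord(
        name="Flavonol A",
        pubchem_cid=1001,
        molecular_weight=302.2,
        ob=55.0,
        dl=0.4,
        caco2=0.6,
        gi_absorption="High",
        druglikeness_flags=(True, True, True, False, False),
    )


def random_graph(rng: random.Random, max_nodes: int = 8):
    """A small random simple graph with uniformly random edge density."""
    n = rng.randint(1, max_nodes)
    p = rng.random()
    edges = [
        (i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < p
    ]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return n, edges, g
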