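import numpy as np
import networkx as nx
import pytest

from bioregions.incidence import IncidenceMatrix, SpeciesClassTable
from bioregions.modularity import Partition, WeightedGraph, modularity_Q


@pytest.fixture
def toy_incidence() -> IncidenceMatrix:
    """3 species x 2 sites with entries [[1,0],[1,1],[0,1]] (species rows)."""
    occ = np.array([[1, 0], [1, 1], [0, 1]]).T  # canonical sites x species
    return IncidenceMatrix(["siteA", "siteB"], ["sp1", "sp2", "sp3"], occ)


@pytest.fixture
def barbell_graph() -> WeightedGraph:
    """Two unit-weight triangles joined by a single bridge edge (m = 7)."""
    edges = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0),
             (3, 4, 1.0), (4, 5, 1.0), (3, 5, 1.0), (2, 3, 1.0)]
    return WeightedGraph(list(range(6)), edges)


@pytest.fixture
def barbell_partition() -> Partition:
    return Partition({0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1})


def set_partitions(items):
    """All set partitions of a list (Bell-number enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def brute_force_best_q(g: WeightedGraph) -> float:
    """Exhaustive modularity maximum over all set partitions of the nodes."""
    best = -np.inf
    for blocks in set_partitions(list(g.nodes)):
        part = Partition({u: i for i, blk in enumerate(blocks) for u in blk})
        best = max(best, modularity_Q(g, part))
    return best


def random_weighted_graph(seed: int) -> WeightedGraph | None:
    """Seeded Erdos-Renyi graph (4-8 nodes) with uniform weights, or None."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 9))
    gx = nx.gnp_random_graph(n, 0.5, seed=seed)
    if gx.number_of_edges() == 0:
        return None
    return WeightedGraph(
        list(gx.nodes),
        [(u, v, float(rng.uniform(0.2, 1.0))) for u, v in gx.edges()],
    )


@pytest.fixture
def simple_classes() -> SpeciesClassTable:
    return SpeciesClassTable({"sp1": "ME", "sp2": "COSMP", "sp3": "ATL"})
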