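"""Jaccard dissimilarity and percolation thresholding of the site network.

Sites form a complete weighted graph whose edge weights are Jaccard
dissimilarities between their species assemblages (0 = identical composition,
1 = no shared taxa).  The percolation threshold is found by deleting distance
values in decreasing order — most dissimilar pairs first — and tracking the
average size of the clusters outside the largest one,

    <L> = (1/N) * sum_{l < l_max} l^2 * n_l ,

where n_l is the number of l-site clusters, l_max the (single) largest cluster
excluded from the sum, and N the number of sites outside it.  While the graph
remains connected <L> is 0; the deletion step at which the giant component
first breaks marks the critical distance.  The retained network keeps every
pair strictly more similar than that critical value.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .incidence import IncidenceMatrix

__all__ = [
    "DistanceMatrix",
    "PercolationStep",
    "PercolationResult",
    "jaccard_distances",
    "avg_cluster_size",
    "percolation_threshold",
]

#: Distances are compared after rounding to this many significant digits so
#: that floating-point noise cannot split an intended tie into two deletion
#: steps.
TIE_SIGFIGS = 12


@dataclass
class DistanceMatrix:
    """Symmetric matrix of Jaccard dissimilarities between sites."""

    site_ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.site_ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("distance matrix diagonal is not zero")
        if self.d.min() < -1e-12 or self.d.max() > 1 + 1e-12:
            raise ValueError("Jaccard distances must lie in [0, 1]")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    def pairs(self):
        """Yield (site_i, site_j, distance) over the upper triangle."""
        for i in range(self.n_sites):
            for j in range(i + 1, self.n_sites):
                yield self.site_ids[i], self.site_ids[j], float(self.d[i, j])


@dataclass
class PercolationStep:
    """One deletion step of the percolation trace."""

    removed_value: float
    n_edges_removed: int
    cluster_sizes: tuple[int, ...]
    n_components: int
    largest: int
    avg_cluster_size: float


@dataclass
class PercolationResult:
    """Critical threshold, full deletion trace and the retained network."""

    threshold: float
    trace: list[PercolationStep]
    retained_edges: list[tuple[str, str, float, float]]  # (i, j, distance, similarity)
    site_ids: list[str] = field(default_factory=list)
    degenerate: bool = False
    retention: str = "<"

    @property
    def n_links(self) -> int:
        return len(self.retained_edges)

    def graph(self, *, binary: bool = False) -> nx.Graph:
        """Retained network as a weighted graph (weight = similarity)."""
        g = nx.Graph()
        g.add_nodes_from(self.site_ids)
        for i, j, dist, sim in self.retained_edges:
            g.add_edge(i, j, distance=dist, similarity=sim,
                       weight=1.0 if binary else sim)
        return g


def jaccard_distances(inc: IncidenceMatrix) -> DistanceMatrix:
    """Pairwise Jaccard dissimilarity between site assemblages.

    d(i, j) = 1 - |S_i ∩ S_j| / |S_i ∪ S_j| over the species sets S; a site
    with no species has an undefined distance and is rejected.
    """
    if inc.n_sites < 2:
        raise ValueError("need at least 2 sites for a distance matrix")
    richness = inc.occ.sum(axis=1)
    if (richness == 0).any():
        empty = [s for s, r in zip(inc.site_ids, richness) if r == 0]
        raise ValueError(f"Jaccard distance undefined for empty site(s): {empty}")
    d = squareform(pdist(inc.occ.astype(bool), metric="jaccard"))
    return DistanceMatrix(list(inc.site_ids), d)


def avg_cluster_size(cluster_sizes) -> float:
    """Average cluster size <L> excluding exactly one largest cluster.

    With cluster sizes {l} and multiplicities n_l, one cluster of maximal
    size is set aside; over the N sites in the remaining clusters
    <L> = (1/N) * sum l^2 * n_l.  A fully connected graph (single cluster)
    gives 0.  Ties for the maximum leave the other maximal clusters in the
    sum.
    """
    sizes = sorted(int(s) for s in cluster_sizes)
    if not sizes:
        raise ValueError("empty cluster-size multiset")
    if any(s <= 0 for s in sizes):
        raise ValueError("cluster sizes must be positive")
    rest = sizes[:-1]  # drop one maximal cluster only
    n = sum(rest)
    if n == 0:
        return 0.0
    counts = Counter(rest)
    return sum(l * l * n_l for l, n_l in counts.items()) / n


def _round_sig(x: float, sig: int = TIE_SIGFIGS) -> float:
    if x == 0:
        return 0.0
    return float(np.format_float_positional(
        x, precision=sig, unique=False, fractional=False))


def percolation_threshold(
    dm: DistanceMatrix, *, retention: str = "<"
) -> PercolationResult:
    """Locate the critical distance by decreasing-order edge deletion.

    Starting from the complete graph implied by ``dm``, every edge carrying
    the currently largest distinct distance value is deleted in one step;
    component sizes and <L> are recorded after each step.  The threshold is
    the deleted value at which the graph first fragments.  ``retention``
    selects whether ties with the threshold are kept: the default ``'<'``
    drops them (the fragmenting value itself is not retained), ``'<='``
    keeps them for sensitivity checks.
    """
    if retention not in ("<", "<="):
        raise ValueError("retention must be '<' or '<='")
    n = dm.n_sites
    g = nx.Graph()
    g.add_nodes_from(dm.site_ids)
    edges_by_value: dict[float, list[tuple[str, str, float]]] = {}
    for i, j, dist in dm.pairs():
        g.add_edge(i, j)
        edges_by_value.setdefault(_round_sig(dist), []).append((i, j, dist))

    values = sorted(edges_by_value, reverse=True)
    trace: list[PercolationStep] = []
    threshold: float | None = None
    for value in values:
        batch = edges_by_value[value]
        g.remove_edges_from([(i, j) for i, j, _ in batch])
        sizes = tuple(sorted((len(c) for c in nx.connected_components(g)),
                             reverse=True))
        step = PercolationStep(
            removed_value=value,
            n_edges_removed=len(batch),
            cluster_sizes=sizes,
            n_components=len(sizes),
            largest=sizes[0],
            avg_cluster_size=avg_cluster_size(sizes),
        )
        trace.append(step)
        if threshold is None and sizes[0] < n:
            threshold = value

    if threshold is None:
        # Cannot happen for n >= 2: deleting the final value isolates nodes.
        raise RuntimeError("deletion sequence never fragmented the network")

    # Fragmentation only at the final deletion step means the graph never
    # broke while it still had edges — no informative threshold exists.
    degenerate = threshold == values[-1]
    retained = []
    for value, batch in edges_by_value.items():
        keep = value < threshold if retention == "<" else value <= threshold
        if keep:
            for i, j, dist in batch:
                retained.append((i, j, dist, 1.0 - dist))
    retained.sort(key=lambda e: (e[0], e[1]))
    return PercolationResult(
        threshold=threshold,
        trace=trace,
        retained_edges=retained,
        site_ids=list(dm.site_ids),
        degenerate=degenerate,
        retention=retention,
    )
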