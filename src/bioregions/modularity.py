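"""Modularity maximization by simulated annealing with a configuration null.

The percolation network is partitioned into modules by maximizing
Newman-Girvan modularity

    Q = (1/2m) * sum_ij [A_ij - k_i k_j / 2m] * delta(C_i, C_j)

where A is the (similarity-)weighted adjacency, k the weighted degree, m the
total link weight, and the configuration model supplies the null probability
P_ij = k_i k_j / 2m.  Optimization uses simulated annealing over single-node
reassignments plus collective merge/split proposals, preceded by a
zero-temperature greedy phase over the same move set.  Significance is
assessed against degree-preserving edge rewirings of the observed topology,
and a consensus over independent restarts yields per-node affiliation
frequencies.
"""

from __future__ import annotations

import math
import random
import warnings
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import squareform

__all__ = [
    "WeightedGraph",
    "Partition",
    "SASchedule",
    "ModularityResult",
    "modularity_Q",
    "sa_maximize",
    "null_distribution",
    "consensus",
    "best_partition",
]


@dataclass
class WeightedGraph:
    """Undirected weighted graph over site nodes; no self-loops, w > 0."""

    nodes: list
    edges: list  # (u, v, w)

    def __post_init__(self) -> None:
        seen = set()
        for u, v, w in self.edges:
            if u == v:
                raise ValueError(f"self-loop on node {u!r}")
            if w <= 0:
                raise ValueError(f"non-positive weight on edge ({u!r}, {v!r})")
            key = frozenset((u, v))
            if key in seen:
                raise ValueError(f"duplicate edge ({u!r}, {v!r})")
            seen.add(key)
        node_set = set(self.nodes)
        if len(node_set) != len(self.nodes):
            raise ValueError("duplicate nodes")
        for u, v, _ in self.edges:
            if u not in node_set or v not in node_set:
                raise ValueError(f"edge endpoint not in node list: ({u!r}, {v!r})")

    @property
    def m(self) -> float:
        """Total link weight (m of the modularity formula)."""
        return float(sum(w for _, _, w in self.edges))

    @property
    def n(self) -> int:
        return len(self.nodes)

    def degrees(self) -> dict:
        k = {u: 0.0 for u in self.nodes}
        for u, v, w in self.edges:
            k[u] += w
            k[v] += w
        return k

    def adjacency(self) -> dict:
        adj: dict = {u: {} for u in self.nodes}
        for u, v, w in self.edges:
            adj[u][v] = w
            adj[v][u] = w
        return adj

    @classmethod
    def from_networkx(cls, g: nx.Graph, weight: str = "weight") -> "WeightedGraph":
        edges = [(u, v, float(d.get(weight, 1.0))) for u, v, d in g.edges(data=True)]
        return cls(list(g.nodes), edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_weighted_edges_from(self.edges)
        return g


@dataclass
class Partition:
    """Node -> module label map with canonical integer labels.

    Labels are renumbered 0..k-1 by decreasing module size, ties broken by
    the lexicographically smallest member, so that identical groupings
    compare equal regardless of the labels they were built with.
    """

    mapping: dict

    def __post_init__(self) -> None:
        self.mapping = self._canonicalize(self.mapping)

    @staticmethod
    def _canonicalize(mapping: dict) -> dict:
        groups: dict = {}
        for node, label in mapping.items():
            groups.setdefault(label, []).append(node)
        ordered = sorted(
            groups.values(), key=lambda ns: (-len(ns), min(str(x) for x in ns))
        )
        return {node: i for i, nodes in enumerate(ordered) for node in nodes}

    @property
    def n_modules(self) -> int:
        return len(set(self.mapping.values())) if self.mapping else 0

    def members(self, label: int) -> list:
        return [n for n, l in self.mapping.items() if l == label]

    def modules(self) -> dict:
        out: dict = {}
        for node, label in self.mapping.items():
            out.setdefault(label, set()).add(node)
        return out

    def labels_for(self, nodes) -> list[int]:
        return [self.mapping[n] for n in nodes]

    def __eq__(self, other) -> bool:
        return isinstance(other, Partition) and self.mapping == other.mapping

    def __getitem__(self, node) -> int:
        return self.mapping[node]


@dataclass
class SASchedule:
    """Annealing schedule; None fields are resolved per graph size.

    t0 defaults to 1/(2m); moves_per_t to max(100, n^2) single-node
    proposals; collective_per_t to n merge/split proposals; the ladder is
    geometric with factor ``cooling`` and stops after ``patience``
    temperature steps without improvement of the best Q seen.
    """

    t0: float | None = None
    cooling: float = 0.995
    moves_per_t: int | None = None
    collective_per_t: int | None = None
    patience: int = 50
    max_temps: int = 20000
    greedy_init: bool = True
    cycles: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.cooling < 1:
            raise ValueError("cooling factor must be in (0, 1)")
        if self.cycles < 1:
            raise ValueError("cycles must be >= 1")

    def resolve(self, n: int, m: float) -> "SASchedule":
        # Floor t0 at 0.05: 1/(2m) alone is too cold on small dense graphs
        # to escape the greedy basin (verified against exhaustive search).
        return replace(
            self,
            t0=self.t0 if self.t0 is not None else max(1.0 / (2.0 * m), 0.05),
            moves_per_t=(self.moves_per_t if self.moves_per_t is not None
                         else max(100, n * n)),
            collective_per_t=(self.collective_per_t
                             if self.collective_per_t is not None else n),
        )

    @classmethod
    def reduced(cls) -> "SASchedule":
        """Lighter schedule for null replicates: half the ladder and moves."""
        return cls(cooling=0.99, patience=10, moves_per_t=None,
                   collective_per_t=None, max_temps=2000, cycles=1)


@dataclass
class ModularityResult:
    """Bundle of partition, Q, restart spread, and null-model significance."""

    partition: Partition
    q: float
    restart_qs: list[float] = field(default_factory=list)
    affiliation_freq: dict = field(default_factory=dict)
    null_q: np.ndarray | None = None
    null_mean: float | None = None
    null_sd: float | None = None
    ci95: tuple[float, float] | None = None
    p_value: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.ci95 is None:
            return None
        return self.q > self.ci95[1]


def modularity_Q(g: WeightedGraph, part: Partition) -> float:
    """Modularity of a partition: sum over modules of e_c/m - (d_c/2m)^2."""
    m = g.m
    if m == 0:
        raise ValueError("graph has no edges (m = 0); modularity undefined")
    missing = [u for u in g.nodes if u not in part.mapping]
    if missing:
        raise ValueError(f"partition does not label node(s): {missing}")
    k = g.degrees()
    e_c: dict[int, float] = {}
    d_c: dict[int, float] = {}
    for u in g.nodes:
        c = part[u]
        d_c[c] = d_c.get(c, 0.0) + k[u]
    for u, v, w in g.edges:
        if part[u] == part[v]:
            c = part[u]
            e_c[c] = e_c.get(c, 0.0) + w
    return sum(
        e_c.get(c, 0.0) / m - (d / (2.0 * m)) ** 2 for c, d in d_c.items()
    )


class _SAState:
    """Mutable annealing state with O(degree) incremental Q updates."""

    __slots__ = ("n", "m", "adj", "k", "comm", "d_c", "e_c", "q")

    def __init__(self, g: WeightedGraph, labels: list[int]):
        index = {u: i for i, u in enumerate(g.nodes)}
        self.n = g.n
        self.m = g.m
        self.adj: list[dict[int, float]] = [{} for _ in range(self.n)]
        self.k = [0.0] * self.n
        for u, v, w in g.edges:
            iu, iv = index[u], index[v]
            self.adj[iu][iv] = w
            self.adj[iv][iu] = w
            self.k[iu] += w
            self.k[iv] += w
        self.comm = list(labels)
        self.d_c = [0.0] * self.n
        self.e_c = [0.0] * self.n
        for i in range(self.n):
            self.d_c[self.comm[i]] += self.k[i]
        for u, v, w in g.edges:
            iu, iv = index[u], index[v]
            if self.comm[iu] == self.comm[iv]:
                self.e_c[self.comm[iu]] += w
        self.q = self._full_q()

    def _full_q(self) -> float:
        m = self.m
        return sum(
            self.e_c[c] / m - (self.d_c[c] / (2 * m)) ** 2
            for c in range(self.n)
            if self.d_c[c] > 0 or self.e_c[c] > 0
        )

    def weight_to(self, i: int, c: int) -> float:
        comm = self.comm
        return sum(w for j, w in self.adj[i].items() if comm[j] == c)

    def delta_move(self, i: int, b: int) -> float:
        a = self.comm[i]
        if a == b:
            return 0.0
        w_ia = self.weight_to(i, a)
        w_ib = self.weight_to(i, b)
        ki = self.k[i]
        m = self.m
        return (w_ib - w_ia) / m - ki * (self.d_c[b] - self.d_c[a] + ki) / (
            2 * m * m
        )

    def apply_move(self, i: int, b: int, dq: float) -> None:
        a = self.comm[i]
        self.e_c[a] -= self.weight_to(i, a)
        self.comm[i] = b
        self.e_c[b] += self.weight_to(i, b)
        self.d_c[a] -= self.k[i]
        self.d_c[b] += self.k[i]
        self.q += dq

    def delta_merge(self, a: int, b: int) -> float:
        w_ab = 0.0
        members_a = [i for i in range(self.n) if self.comm[i] == a]
        for i in members_a:
            for j, w in self.adj[i].items():
                if self.comm[j] == b:
                    w_ab += w
        m = self.m
        return w_ab / m - self.d_c[a] * self.d_c[b] / (2 * m * m)

    def apply_merge(self, a: int, b: int, dq: float) -> None:
        w_ab = 0.0
        for i in range(self.n):
            if self.comm[i] == a:
                for j, w in self.adj[i].items():
                    if self.comm[j] == b:
                        w_ab += w
                self.comm[i] = b
        self.e_c[b] += self.e_c[a] + w_ab
        self.e_c[a] = 0.0
        self.d_c[b] += self.d_c[a]
        self.d_c[a] = 0.0
        self.q += dq

    def free_label(self) -> int | None:
        for c in range(self.n):
            if self.d_c[c] == 0.0 and self.e_c[c] == 0.0:
                return c
        return None  # every community occupied (all-singleton partition)

    def snapshot(self) -> list[int]:
        return list(self.comm)


def _greedy_phase(state: _SAState, rng: random.Random) -> None:
    """Zero-temperature descent: accept only improving node moves/merges."""
    improved = True
    while improved:
        improved = False
        order = list(range(state.n))
        rng.shuffle(order)
        for i in order:
            targets = {state.comm[j] for j in state.adj[i]}
            targets.discard(state.comm[i])
            best_b, best_dq = -1, 1e-12
            for b in targets:
                dq = state.delta_move(i, b)
                if dq > best_dq:
                    best_b, best_dq = b, dq
            if best_b >= 0:
                state.apply_move(i, best_b, best_dq)
                improved = True
        labels = sorted({c for c in state.comm})
        rng.shuffle(labels)
        for a in labels:
            if state.d_c[a] == 0.0:
                continue
            neigh_comms = set()
            for i in range(state.n):
                if state.comm[i] == a:
                    neigh_comms.update(state.comm[j] for j in state.adj[i])
            neigh_comms.discard(a)
            for b in neigh_comms:
                dq = state.delta_merge(a, b)
                if dq > 1e-12:
                    state.apply_merge(a, b, dq)
                    improved = True
                    break


def _attempt_split(state: _SAState, rng: random.Random, t: float) -> None:
    """Propose splitting one module by a random bisection refined greedily."""
    occupied = [c for c in range(state.n) if state.d_c[c] > 0.0]
    candidates = [c for c in occupied if sum(1 for x in state.comm if x == c) >= 2]
    if not candidates:
        return
    c = rng.choice(candidates)
    members = [i for i in range(state.n) if state.comm[i] == c]
    new = state.free_label()
    if new is None:
        return
    before_q = state.q
    before = state.snapshot()
    moved = [i for i in members if rng.random() < 0.5]
    if not moved or len(moved) == len(members):
        return
    for i in moved:
        state.apply_move(i, new, state.delta_move(i, new))
    # one refinement sweep between the two halves
    for i in members:
        other = new if state.comm[i] == c else c
        dq = state.delta_move(i, other)
        if dq > 0:
            state.apply_move(i, other, dq)
    dq_total = state.q - before_q
    if dq_total >= 0 or rng.random() < math.exp(dq_total / t):
        return
    # reject: move members back to their original halves
    for i in members:
        if state.comm[i] != before[i]:
            state.apply_move(i, before[i], state.delta_move(i, before[i]))
    state.q = before_q


def sa_maximize(
    g: WeightedGraph,
    schedule: SASchedule | None = None,
    seed: int = 0,
) -> tuple[Partition, float]:
    """Heuristic modularity maximization by simulated annealing.

    Starts from singletons, runs a greedy phase (same move set at zero
    temperature), then anneals with geometric cooling, accepting a proposal
    with probability min(1, exp(dQ/T)).  Returns the best partition ever
    visited and its Q.  Deterministic for a given seed.
    """
    if g.m == 0:
        # Edgeless graph: modularity undefined; every grouping equivalent.
        return Partition({u: 0 for u in g.nodes}), 0.0
    schedule = (schedule or SASchedule()).resolve(g.n, g.m)
    rng = random.Random(seed)

    best_q = -math.inf
    best: list[int] = list(range(g.n))
    for _ in range(schedule.cycles):
        state = _SAState(g, list(range(g.n)))
        if schedule.greedy_init:
            _greedy_phase(state, rng)
        if state.q > best_q:
            best_q, best = state.q, state.snapshot()
        t = schedule.t0
        stale = 0
        for _ in range(schedule.max_temps):
            for _ in range(schedule.moves_per_t):
                i = rng.randrange(state.n)
                nbrs = list(state.adj[i])
                if nbrs and rng.random() < 0.9:
                    b = state.comm[nbrs[rng.randrange(len(nbrs))]]
                else:
                    b = state.free_label()  # allow breaking a node out alone
                if b is None or b == state.comm[i]:
                    continue
                dq = state.delta_move(i, b)
                if dq >= 0 or rng.random() < math.exp(dq / t):
                    state.apply_move(i, b, dq)
            for _ in range(schedule.collective_per_t):
                if rng.random() < 0.5:
                    occupied = [c for c in range(state.n) if state.d_c[c] > 0.0]
                    if len(occupied) >= 2:
                        a, b = rng.sample(occupied, 2)
                        dq = state.delta_merge(a, b)
                        if dq >= 0 or rng.random() < math.exp(dq / t):
                            state.apply_merge(a, b, dq)
                else:
                    _attempt_split(state, rng, t)
            if state.q > best_q + 1e-12:
                best_q = state.q
                best = state.snapshot()
                stale = 0
            else:
                stale += 1
                if stale >= schedule.patience:
                    break
            t *= schedule.cooling

    part = Partition({u: best[i] for i, u in enumerate(g.nodes)})
    q = modularity_Q(g, part)
    # Never return worse than the trivial partitions (Q=0 for one module).
    if q < 0.0:
        return Partition({u: 0 for u in g.nodes}), 0.0
    return part, q


def best_partition(
    g: WeightedGraph,
    n_restarts: int = 10,
    schedule: SASchedule | None = None,
    seed: int = 0,
) -> tuple[Partition, float, list[Partition], list[float]]:
    """Run ``n_restarts`` independent SA restarts; return the best and all."""
    parts: list[Partition] = []
    qs: list[float] = []
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n_restarts):
        sub = int(child.generate_state(1)[0] % (2**31))
        p, q = sa_maximize(g, schedule, seed=sub)
        parts.append(p)
        qs.append(q)
    ibest = int(np.argmax(qs))
    return parts[ibest], qs[ibest], parts, qs


def _rewire(g: WeightedGraph, rng: np.random.Generator) -> WeightedGraph:
    """Degree-preserving rewiring; weights reshuffled onto the new edges."""
    gx = g.to_networkx()
    n_edges = gx.number_of_edges()
    nswap = 10 * n_edges
    try:
        nx.double_edge_swap(
            gx, nswap=nswap, max_tries=100 * nswap,
            seed=int(rng.integers(2**31)),
        )
    except nx.NetworkXError:
        warnings.warn(
            "graph too sparse for degree-preserving rewiring; "
            "falling back to weight permutation", stacklevel=2,
        )
    weights = [w for _, _, w in g.edges]
    rng.shuffle(weights)
    edges = [(u, v, w) for (u, v), w in zip(gx.edges(), weights)]
    return WeightedGraph(list(g.nodes), edges)


def null_distribution(
    g: WeightedGraph,
    q_obs: float,
    n_rand: int = 1000,
    seed: int = 0,
    schedule: SASchedule | None = None,
) -> dict:
    """Maximized-Q null distribution under degree-preserving randomization.

    Each replicate rewires the observed topology by double-edge swaps (10x
    the edge count), shuffles the observed weights onto the rewired edges,
    and maximizes modularity with a reduced annealing schedule.  Returns the
    sample with mean, SD, percentile 95% CI and the add-one empirical
    p-value for ``q_obs``.
    """
    if not g.edges:
        raise ValueError("null distribution undefined for an edgeless graph")
    schedule = schedule or SASchedule.reduced()
    rng = np.random.default_rng(seed)
    null_q = np.empty(n_rand)
    for r in range(n_rand):
        rep = _rewire(g, rng)
        _, null_q[r] = sa_maximize(rep, schedule, seed=int(rng.integers(2**31)))
    lo, hi = np.percentile(null_q, [2.5, 97.5])
    p = (1 + int((null_q >= q_obs - 1e-12).sum())) / (n_rand + 1)
    return {
        "null_q": null_q,
        "null_mean": float(null_q.mean()),
        "null_sd": float(null_q.std(ddof=1)) if n_rand > 1 else 0.0,
        "ci95": (float(lo), float(hi)),
        "p_value": float(p),
        "n_rand": int(n_rand),
    }


def consensus(partitions: list[Partition]) -> tuple[Partition, dict]:
    """Majority-rule consensus over restart partitions.

    Builds the node co-classification matrix, groups nodes by average-link
    hierarchical clustering cut at 0.5 co-assignment, and reports per node
    the fraction of restarts whose (best-matched) module agrees with the
    consensus label.  Nodes below 0.9 agreement are the unstable ones.
    """
    if len(partitions) < 3:
        raise ValueError("consensus needs at least 3 restart partitions")
    nodes = sorted(partitions[0].mapping, key=str)
    node_set = set(nodes)
    for p in partitions[1:]:
        if set(p.mapping) != node_set:
            raise ValueError("partitions cover different node sets")
    n = len(nodes)
    labels = np.array([[p[u] for u in nodes] for p in partitions])
    co = (labels[:, :, None] == labels[:, None, :]).mean(axis=0)
    if n == 1:
        cons = Partition({nodes[0]: 0})
        return cons, {nodes[0]: 1.0}
    z = linkage(squareform(1.0 - co, checks=False), method="average")
    flat = fcluster(z, t=0.5, criterion="distance")
    cons = Partition(dict(zip(nodes, (int(x) for x in flat))))

    agree = np.zeros(n)
    cons_labels = np.array([cons[u] for u in nodes])
    k_cons = cons_labels.max() + 1
    for row in labels:
        k_r = row.max() + 1
        overlap = np.zeros((k_r, k_cons))
        for lr, lc in zip(row, cons_labels):
            overlap[lr, lc] += 1
        ri, ci = linear_sum_assignment(-overlap)
        mapping = dict(zip(ri, ci))
        mapped = np.array([mapping.get(lr, -1) for lr in row])
        agree += mapped == cons_labels
    freq = {u: float(a / len(partitions)) for u, a in zip(nodes, agree)}
    return cons, freq
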