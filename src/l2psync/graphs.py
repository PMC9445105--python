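"""Random and special graph topologies for coupled-oscillator experiments.

The workhorse generator is a Newman–Watts–Strogatz (NWS) variant with an
extra integer parameter ``M``: starting from a ring lattice in which every
node is joined to its ``k_nws`` nearest neighbours, each non-edge of the
initial lattice is offered independently in ``M`` successive rounds with
per-round probability ``p / (n - k_nws - 1)``.  The underlying cycle keeps
every realisation connected, and the shortcut density interpolates between
the ring (hard to synchronise) and dense graphs (easy to synchronise).

Also provided: the special topologies used for topology-contrast
experiments (ring, path, complete, bounded-degree random tree), the five
basic graph statistics used as classifier features, connected induced
subgraph sampling by random BFS growth, and a Weisfeiler–Leman hash for
non-isomorphism bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "NwsParams",
    "GraphFeatures",
    "make_topology",
    "generate_nws_plus",
    "expected_edge_count",
    "graph_features",
    "sample_connected_induced_subgraph",
    "wl_hash",
    "save_edgelist",
    "load_edgelist",
]


@dataclass(frozen=True)
class Graph:
    """Simple undirected graph with nodes 0..n-1 in fixed creation order.

    The node order is canonical for feature flattening: dynamics matrices
    and adjacency encodings always use it.
    """

    num_nodes: int
    edges: frozenset  # frozenset of frozenset({u, v}) pairs

    def __post_init__(self):
        for e in self.edges:
            u, v = tuple(e)
            if u == v:
                raise ValueError("self-loop in edge set")
            if not (0 <= u < self.num_nodes and 0 <= v < self.num_nodes):
                raise ValueError("edge endpoint outside node range")

    @staticmethod
    def from_edges(num_nodes: int, edges: Iterable[tuple[int, int]]) -> "Graph":
        return Graph(num_nodes, frozenset(frozenset((int(u), int(v))) for u, v in edges))

    @property
    def num_edges(self) -> int:
        return len(self.edges)

    def edge_list(self) -> list[tuple[int, int]]:
        """Edges as sorted (u, v) tuples with u < v, in lexicographic order."""
        return sorted(tuple(sorted(e)) for e in self.edges)

    def adjacency(self, n_pad: int | None = None, dtype=np.float64) -> np.ndarray:
        """Dense adjacency matrix, optionally zero-padded to ``n_pad`` nodes."""
        n = self.num_nodes if n_pad is None else n_pad
        if n < self.num_nodes:
            raise ValueError("n_pad smaller than num_nodes")
        A = np.zeros((n, n), dtype=dtype)
        for u, v in self.edge_list():
            A[u, v] = A[v, u] = 1
        return A

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.num_nodes))
        g.add_edges_from(self.edge_list())
        return g

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.num_nodes, dtype=int)
        for u, v in self.edge_list():
            deg[u] += 1
            deg[v] += 1
        return deg

    def neighbors(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.num_nodes)]
        for u, v in self.edge_list():
            nbrs[u].append(v)
            nbrs[v].append(u)
        return nbrs

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_networkx())

    def induced_subgraph(self, nodes: Iterable[int]) -> "Graph":
        """Induced subgraph on ``nodes``, relabelled 0..len(nodes)-1 in the given order."""
        order = list(nodes)
        pos = {v: i for i, v in enumerate(order)}
        if len(pos) != len(order):
            raise ValueError("duplicate nodes in subset")
        sub = [
            (pos[u], pos[v])
            for u, v in self.edge_list()
            if u in pos and v in pos
        ]
        return Graph.from_edges(len(order), sub)


@dataclass(frozen=True)
class NwsParams:
    """Parameters of the NWS-plus random graph model.

    n: node count; k_nws: even initial ring-lattice degree; p: shortcut
    probability parameter (per-round pair probability is p/(n-k_nws-1));
    M: number of independent shortcut-adding rounds.
    """

    n: int
    k_nws: int = 2
    p: float = 0.65
    M: int = 1

    def __post_init__(self):
        if self.n < 3:
            raise ValueError("n must be >= 3")
        if self.k_nws % 2 != 0 or not (2 <= self.k_nws < self.n):
            raise ValueError("k_nws must be even with 2 <= k_nws < n")
        if not (0 <= self.p):
            raise ValueError("p must be >= 0")
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.per_round_probability > 1:
            raise ValueError(
                f"per-round probability p/(n-k_nws-1) = {self.per_round_probability:.4g} > 1"
            )

    @property
    def per_round_probability(self) -> float:
        return self.p / (self.n - self.k_nws - 1)


@dataclass(frozen=True)
class GraphFeatures:
    """The five basic graph statistics used as classifier inputs."""

    num_edges: int
    min_degree: int
    max_degree: int
    diameter: int
    num_nodes: int

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.num_edges, self.min_degree, self.max_degree, self.diameter, self.num_nodes],
            dtype=np.float64,
        )

    @staticmethod
    def names() -> list[str]:
        return ["num_edges", "min_degree", "max_degree", "diameter", "num_nodes"]


def _ring_lattice_edges(n: int, k: int) -> list[tuple[int, int]]:
    edges = []
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            edges.append((min(i, j), max(i, j)))
    return sorted(set(edges))


def make_topology(kind: str, n: int, max_degree: int | None = None, rng=None) -> Graph:
    """Build one of the special topologies: ring, path, complete, random_tree.

    ``random_tree`` grows a tree by uniform random attachment (each new node
    joins a uniformly chosen existing node) and regrows until the maximum
    degree is at most ``max_degree``.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if kind == "ring":
        return Graph.from_edges(n, [(i, (i + 1) % n) for i in range(n)])
    if kind == "path":
        return Graph.from_edges(n, [(i, i + 1) for i in range(n - 1)])
    if kind == "complete":
        return Graph.from_edges(n, [(i, j) for i in range(n) for j in range(i + 1, n)])
    if kind == "random_tree":
        if max_degree is None or max_degree < 2:
            raise ValueError("random_tree requires max_degree >= 2")
        rng = np.random.default_rng(rng)
        while True:
            deg = np.zeros(n, dtype=int)
            edges = []
            ok = True
            for v in range(1, n):
                u = int(rng.integers(0, v))
                edges.append((u, v))
                deg[u] += 1
                deg[v] += 1
                if deg[u] > max_degree:
                    ok = False
                    break
            if ok and deg.max() <= max_degree:
                return Graph.from_edges(n, edges)
    raise ValueError(f"unknown topology kind: {kind!r}")


def generate_nws_plus(params: NwsParams, rng=None) -> Graph:
    """Draw one NWS-plus graph: ring lattice plus M rounds of random shortcuts."""
    rng = np.random.default_rng(rng)
    n, k = params.n, params.k_nws
    lattice = _ring_lattice_edges(n, k)
    lattice_set = set(lattice)
    non_edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if (i, j) not in lattice_set
    ]
    q = params.per_round_probability
    edges = list(lattice)
    if non_edges and q > 0:
        # One Bernoulli draw per (non-edge, round); a pair is added if it
        # succeeds in any round (duplicates collapse in the simple graph).
        m = len(non_edges)
        hit = np.zeros(m, dtype=bool)
        for _ in range(params.M):
            hit |= rng.random(m) < q
        edges.extend(e for e, h in zip(non_edges, hit) if h)
    return Graph.from_edges(n, edges)


def expected_edge_count(params: NwsParams, method: str = "exact") -> float:
    """Expected number of edges of the NWS-plus model.

    ``exact``: nk/2 + [C(n,2) - nk/2] * (1 - (1 - p/(n-k-1))^M).
    ``leading``: nk/2 + n^2 p M / (2 (n-k-1)), the leading-order
    approximation (accurate for small per-round probability).
    """
    n, k, p, M = params.n, params.k_nws, params.p, params.M
    lattice = n * k / 2
    if method == "exact":
        non_edges = math.comb(n, 2) - lattice
        q = params.per_round_probability
        return lattice + non_edges * (1 - (1 - q) ** M)
    if method == "leading":
        return lattice + n * n * p * M / (2 * (n - k - 1))
    raise ValueError(f"unknown method: {method!r}")


def graph_features(G: Graph) -> GraphFeatures:
    """Compute the five basic statistics; raises on disconnected graphs."""
    g = G.to_networkx()
    if not nx.is_connected(g):
        raise ValueError("graph is disconnected; diameter undefined")
    deg = G.degrees()
    return GraphFeatures(
        num_edges=G.num_edges,
        min_degree=int(deg.min()),
        max_degree=int(deg.max()),
        diameter=int(nx.diameter(g)),
        num_nodes=G.num_nodes,
    )


def sample_connected_induced_subgraph(G: Graph, n0: int, rng=None) -> list[int]:
    """Sample n0 nodes whose induced subgraph is connected, by random BFS growth.

    A uniform seed node is chosen, then nodes are added one at a time by
    uniform choice among the neighbours of the current set.
    """
    if n0 > G.num_nodes:
        raise ValueError("n0 exceeds number of nodes")
    if n0 < 1:
        raise ValueError("n0 must be >= 1")
    rng = np.random.default_rng(rng)
    nbrs = G.neighbors()
    seed = int(rng.integers(0, G.num_nodes))
    chosen = [seed]
    in_set = {seed}
    frontier = set(nbrs[seed])
    while len(chosen) < n0:
        if not frontier:
            raise RuntimeError("graph is disconnected; cannot grow subgraph")
        v = sorted(frontier)[int(rng.integers(0, len(frontier)))]
        chosen.append(v)
        in_set.add(v)
        frontier.discard(v)
        frontier.update(u for u in nbrs[v] if u not in in_set)
    return chosen


def wl_hash(G: Graph, iterations: int = 3) -> str:
    """Weisfeiler–Leman colour-refinement hash; equal for isomorphic graphs.

    Used for dataset deduplication.  WL is not a complete isomorphism
    invariant, but collisions between non-isomorphic graphs are vanishingly
    rare at the sizes used here.
    """
    import warnings

    with warnings.catch_warnings():
        # networkx >= 3.5 warns once about a historical hash change; the hash
        # is only used for within-run deduplication, so the value is immaterial.
        warnings.simplefilter("ignore", UserWarning)
        return nx.weisfeiler_lehman_graph_hash(G.to_networkx(), iterations=iterations)


def save_edgelist(G: Graph, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# nodes={G.num_nodes}\n")
        for u, v in G.edge_list():
            fh.write(f"{u} {v}\n")


def load_edgelist(path) -> Graph:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("# nodes="):
            raise ValueError(f"{path}: missing '# nodes=<n>' header")
        n = int(header.split("=", 1)[1])
        edges = []
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            u, v = line.split()
            edges.append((int(u), int(v)))
    return Graph.from_edges(n, edges)
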