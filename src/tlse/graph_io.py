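"""Edge-list I/O and basic services for undirected simple graphs.

Networks are plain undirected simple graphs over opaque string labels —
the natural representation of a protein-protein interaction network, in
which nodes are proteins and an (unweighted, undirected) edge records a
physical interaction.  The interchange format is a whitespace/tab
separated two-column edge list; lines starting with ``#`` are comments
and extra columns are ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "EdgeListParseError",
    "read_edge_list",
    "write_edge_list",
    "connected_components",
    "sample_non_edges",
]


class EdgeListParseError(ValueError):
    """Raised for malformed edge-list lines; carries the line number."""


@dataclass
class Network:
    """An undirected simple graph: ordered node labels plus a set of edges.

    Node order is deterministic (first occurrence).  Edges are stored as
    index pairs ``(i, j)`` with ``i < j``; no self-loops or duplicates.
    """

    nodes: list[str]
    edges: list[tuple[int, int]]
    _index: dict[str, int] = field(repr=False, default_factory=dict)
    _edge_set: set[tuple[int, int]] = field(repr=False, default_factory=set)

    def __post_init__(self) -> None:
        if not self._index:
            self._index = {v: i for i, v in enumerate(self.nodes)}
        if not self._edge_set:
            self._edge_set = set(self.edges)
        if len(self._index) != len(self.nodes):
            raise ValueError("duplicate node labels")
        for i, j in self.edges:
            if i == j:
                raise ValueError("self-loop in edge list")
            if not (0 <= i < j < len(self.nodes)):
                raise ValueError("edge endpoint out of range or not canonical")
        if len(self._edge_set) != len(self.edges):
            raise ValueError("duplicate edges")

    # -- constructors -------------------------------------------------
    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Sequence[str] | None = None,
    ) -> "Network":
        """Build a network from labeled edges, deduplicating and dropping
        self-loops.  ``nodes`` may pre-seed the node order (and include
        isolated nodes)."""
        order: list[str] = []
        index: dict[str, int] = {}
        if nodes is not None:
            for v in nodes:
                if v not in index:
                    index[v] = len(order)
                    order.append(v)
        edge_set: set[tuple[int, int]] = set()
        edge_list: list[tuple[int, int]] = []
        dropped_loops = dropped_dups = 0
        for a, b in edges:
            for v in (a, b):
                if v not in index:
                    index[v] = len(order)
                    order.append(v)
            if a == b:
                dropped_loops += 1
                continue
            i, j = sorted((index[a], index[b]))
            if (i, j) in edge_set:
                dropped_dups += 1
                continue
            edge_set.add((i, j))
            edge_list.append((i, j))
        if dropped_loops or dropped_dups:
            logger.info(
                "dropped %d self-loop(s) and %d duplicate edge(s)",
                dropped_loops,
                dropped_dups,
            )
        return cls(nodes=order, edges=edge_list, _index=index, _edge_set=edge_set)

    # -- basic queries ------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def index_of(self, label: str) -> int:
        return self._index[label]

    def has_edge(self, a: str, b: str) -> bool:
        i, j = self._index[a], self._index[b]
        return (min(i, j), max(i, j)) in self._edge_set

    def has_edge_idx(self, i: int, j: int) -> bool:
        return (min(i, j), max(i, j)) in self._edge_set

    def edge_labels(self) -> list[tuple[str, str]]:
        return [(self.nodes[i], self.nodes[j]) for i, j in self.edges]

    def edge_array(self) -> np.ndarray:
        """Edges as an (m, 2) int array (empty -> shape (0, 2))."""
        return np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def adjacency_lists(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def adjacency_matrix(self):
        """Sparse CSR adjacency (0/1, symmetric)."""
        from scipy.sparse import csr_matrix

        e = self.edge_array()
        n = self.n_nodes
        data = np.ones(2 * len(e))
        rows = np.concatenate([e[:, 0], e[:, 1]])
        cols = np.concatenate([e[:, 1], e[:, 0]])
        return csr_matrix((data, (rows, cols)), shape=(n, n))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edge_labels())
        return g

    def n_non_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2 - self.n_edges


def read_edge_list(path: str | Path) -> Network:
    """Read a two-column edge list; '#'-lines are comments, extra columns
    ignored, duplicates and self-loops dropped (logged)."""
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(tokens)}"
                )
            edges.append((tokens[0], tokens[1]))
    return Network.from_edges(edges)


def write_edge_list(net: Network, path: str | Path) -> None:
    """Write the network as a two-column TSV edge list."""
    with open(path, "w") as fh:
        for a, b in net.edge_labels():
            fh.write(f"{a}\t{b}\n")


def connected_components(net: Network) -> list[Network]:
    """Partition into maximal connected subgraphs, largest first
    (ties broken by first node occurrence); isolated nodes form
    singleton components."""
    adj = net.adjacency_lists()
    comp = np.full(net.n_nodes, -1, dtype=np.int64)
    comps: list[list[int]] = []
    for start in range(net.n_nodes):
        if comp[start] >= 0:
            continue
        cid = len(comps)
        stack = [start]
        comp[start] = cid
        members = [start]
        while stack:
            v = stack.pop()
            for w in adj[v]:
                if comp[w] < 0:
                    comp[w] = cid
                    stack.append(w)
                    members.append(w)
        comps.append(sorted(members))
    order = sorted(range(len(comps)), key=lambda c: (-len(comps[c]), comps[c][0]))
    out = []
    for c in order:
        members = comps[c]
        labels = [net.nodes[i] for i in members]
        member_set = set(members)
        sub_edges = [
            (net.nodes[i], net.nodes[j]) for i, j in net.edges if i in member_set
        ]
        out.append(Network.from_edges(sub_edges, nodes=labels))
    return out


def _non_edge_pool(net: Network) -> np.ndarray:
    """All non-adjacent pairs as an (k, 2) index array (i < j)."""
    n = net.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    mask = np.ones(len(iu), dtype=bool)
    if net.n_edges:
        e = net.edge_array()
        # linear index of the upper triangle for O(1) membership
        lin_edges = e[:, 0] * n + e[:, 1]
        lin_all = iu * n + ju
        mask = ~np.isin(lin_all, lin_edges)
    return np.column_stack([iu[mask], ju[mask]])


def sample_non_edge_indices(
    net: Network, count: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform sample of ``count`` distinct non-adjacent index pairs."""
    total = net.n_non_edges()
    if count > total:
        raise ValueError(f"requested {count} non-edges but only {total} exist")
    if count == 0:
        return np.empty((0, 2), dtype=np.int64)
    n = net.n_nodes
    if n * (n - 1) // 2 <= 5_000_000:
        pool = _non_edge_pool(net)
        pick = rng.choice(len(pool), size=count, replace=False)
        return pool[np.sort(pick)]
    # large graphs: rejection sampling
    chosen: set[tuple[int, int]] = set()
    while len(chosen) < count:
        i = int(rng.integers(0, n))
        j = int(rng.integers(0, n))
        if i == j:
            continue
        i, j = min(i, j), max(i, j)
        if (i, j) in chosen or net.has_edge_idx(i, j):
            continue
        chosen.add((i, j))
    return np.asarray(sorted(chosen), dtype=np.int64)


def sample_non_edges(net: Network, count: int, seed: int) -> list[tuple[str, str]]:
    """Uniformly sampled distinct non-adjacent label pairs, reproducible
    for a given seed."""
    rng = np.random.default_rng(seed)
    idx = sample_non_edge_indices(net, count, rng)
    return [(net.nodes[i], net.nodes[j]) for i, j in idx]
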