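"""Social interaction networks: Moore-neighborhood torus and small-world rewiring.

Agents sit on the nodes of an undirected graph.  The base topology is a
W x H cellular-automata lattice in which every cell is linked to its eight
Moore neighbors, with periodic boundaries (a torus), so every node has
degree exactly 8 and e = 4v.  A small-world variant is derived by visiting
each lattice edge and, with probability rho, replacing one uniformly chosen
endpoint by a uniformly chosen new node; node and edge counts are preserved
exactly so the two network types are directly comparable.

Node ids are row-major: node = row * W + col, rows and columns 0-based,
wrap-around by modular arithmetic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SocialNetwork",
    "build_lattice",
    "rewire_to_small_world",
    "neighbors",
]

#: Moore neighborhood offsets (row, col).
MOORE_OFFSETS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)

MIN_SIDE = 5


@dataclass
class SocialNetwork:
    """Undirected simple graph over v = W*H agents."""

    W: int
    H: int
    net_type: str  # "cellular_automata" | "small_world" | "custom"
    edges: np.ndarray  # (e, 2) int array, u < w per row
    rho: float = 0.0
    _adj: list[np.ndarray] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.edges = np.sort(self.edges, axis=1)
        # canonical row order keeps replay byte-identical
        order = np.lexsort((self.edges[:, 1], self.edges[:, 0]))
        self.edges = self.edges[order]
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-loops are not allowed")
        if len(np.unique(self.edges, axis=0)) != len(self.edges):
            raise ValueError("duplicate edges are not allowed")
        if self.edges.size and (self.edges.min() < 0 or self.edges.max() >= self.v):
            raise ValueError("edge endpoint outside node range")

    @property
    def v(self) -> int:
        """Number of nodes."""
        return self.W * self.H

    @property
    def e(self) -> int:
        """Number of edges."""
        return len(self.edges)

    @property
    def nodes(self) -> np.ndarray:
        return np.arange(self.v)

    def _build_adj(self) -> list[np.ndarray]:
        if self._adj is None:
            adj: list[list[int]] = [[] for _ in range(self.v)]
            for u, w in self.edges:
                adj[u].append(int(w))
                adj[w].append(int(u))
            self._adj = [np.array(sorted(a), dtype=np.int64) for a in adj]
        return self._adj

    def neighbors(self, node: int) -> np.ndarray:
        """Adjacency list of ``node`` (sorted, 0-based ids)."""
        if not 0 <= node < self.v:
            raise KeyError(f"unknown node {node}; valid ids are 0..{self.v - 1}")
        return self._build_adj()[node]

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.v, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(u), int(w)) for u, w in self.edges}

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` with all nodes present."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(self.v))
        g.add_edges_from(map(tuple, self.edges))
        return g

    @classmethod
    def from_edges(cls, edges, v: int | None = None, W: int | None = None,
                   H: int | None = None, net_type: str = "custom") -> "SocialNetwork":
        """Build a network from an explicit edge list (fixtures, imports).

        Either (W, H) or v must be given; with only v the node set is laid
        out as a 1 x v strip purely for bookkeeping.
        """
        if W is None or H is None:
            if v is None:
                raise ValueError("provide either v or both W and H")
            W, H = int(v), 1
        return cls(W=W, H=H, net_type=net_type, edges=np.asarray(edges))

    def save(self, path: str | Path) -> None:
        """Write a plain-text edge list with a JSON header comment line."""
        header = json.dumps(
            {"W": self.W, "H": self.H, "type": self.net_type, "rho": self.rho}
        )
        with open(path, "w") as fh:
            fh.write(f"# {header}\n")
            for u, w in self.edges:
                fh.write(f"{u}\t{w}\n")

    @classmethod
    def load(cls, path: str | Path) -> "SocialNetwork":
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("# "):
                raise ValueError("edge-list file must start with a '# {json}' header")
            meta = json.loads(first[2:])
            edges = [tuple(map(int, line.split("\t"))) for line in fh if line.strip()]
        return cls(W=meta["W"], H=meta["H"], net_type=meta["type"],
                   edges=np.asarray(edges, dtype=np.int64), rho=meta.get("rho", 0.0))


def build_lattice(W: int, H: int, pattern: str = "moore") -> SocialNetwork:
    """Build the W x H cellular-automata lattice (Moore torus).

    Every node connects to its eight surrounding cells with periodic
    boundaries, giving degree 8 everywhere and e = 4*W*H.
    """
    if pattern != "moore":
        raise ValueError(
            f"only the Moore neighborhood pattern is implemented, got {pattern!r}"
        )
    if W < MIN_SIDE or H < MIN_SIDE:
        raise ValueError(
            f"lattice must be at least {MIN_SIDE}x{MIN_SIDE} for the "
            f"degree-8 Moore torus, got {W}x{H}"
        )
    edges = []
    for r in range(H):
        for c in range(W):
            u = r * W + c
            for dr, dc in MOORE_OFFSETS:
                w = ((r + dr) % H) * W + ((c + dc) % W)
                if u < w:
                    edges.append((u, w))
    return SocialNetwork(W=W, H=H, net_type="cellular_automata",
                         edges=np.asarray(edges, dtype=np.int64))


def rewire_to_small_world(
    lattice: SocialNetwork,
    rho: float,
    rng: np.random.Generator,
    max_attempts: int = 1000,
) -> SocialNetwork:
    """Derive a small-world network by probabilistic edge rewiring.

    Each edge is independently rewired with probability ``rho``: one of its
    two endpoints (uniform coin) is kept and the other replaced by a node
    drawn uniformly at random.  Replacements that would create a self-loop
    or duplicate an existing edge are redrawn so that v and e are conserved
    exactly.  ``rho = 0`` returns a graph identical to the input.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError(f"rewiring probability must be in [0, 1], got {rho}")
    v = lattice.v
    edge_set = lattice.edge_set()
    edges = [tuple(map(int, row)) for row in lattice.edges]
    for k, (u, w) in enumerate(edges):
        if rng.random() >= rho:
            continue
        keep = u if rng.random() < 0.5 else w
        edge_set.discard((u, w))
        for _ in range(max_attempts):
            new = int(rng.integers(0, v))
            a, b = (keep, new) if keep < new else (new, keep)
            if new != keep and (a, b) not in edge_set:
                edges[k] = (a, b)
                edge_set.add((a, b))
                break
        else:  # pathologically saturated neighborhood: keep the original
            edge_set.add((u, w))
    return SocialNetwork(W=lattice.W, H=lattice.H, net_type="small_world",
                         edges=np.asarray(edges, dtype=np.int64), rho=rho)


def neighbors(net: SocialNetwork, node: int) -> np.ndarray:
    """Adjacency list of ``node`` in ``net``."""
    return net.neighbors(node)
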