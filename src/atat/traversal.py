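"""Embedding-weighted lattice graph and shortest-path traversal.

Vertices are in-tissue spots; edges join hexagonal lattice neighbors
and carry the Euclidean distance between the endpoints' tile
embeddings.  The traversal between two user anchors is the lattice path
of minimum total edge weight — it follows visually homogeneous tissue
and crosses layer boundaries only where it must, while respecting spot
adjacency so no spot is skipped.

Ties between equal-cost paths are broken by fewest spots, then by the
lexicographically smallest spot-id sequence, so the traversal is
reproducible across runs and platforms.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .embedder import EmbeddingSet
from .errors import ContractError, InvalidArgumentError, NoPathError
from .grids import SpotGrid


@dataclass
class TraversalPath:
    """An ordered, adjacency-respecting spot sequence P* from a to b."""

    spots: list[str]
    cost: float

    def __post_init__(self) -> None:
        if len(set(self.spots)) != len(self.spots):
            raise InvalidArgumentError("path repeats a spot")
        if self.cost < 0:
            raise InvalidArgumentError("path cost must be nonnegative")

    @property
    def k(self) -> int:
        """Path length |P*| in spots (the number of assignment sets)."""
        return len(self.spots)


@dataclass
class LatticeGraph:
    """Undirected lattice graph with embedding-distance edge weights."""

    graph: nx.Graph

    @property
    def vertices(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]


def lattice_neighbors(grid: SpotGrid, spot: str) -> set[str]:
    """In-tissue spots at array offsets (0, ±2), (±1, ±1) from ``spot``."""
    return grid.neighbors(spot)


def build_graph(grid: SpotGrid, emb: EmbeddingSet) -> LatticeGraph:
    """One edge per adjacent in-tissue pair, weighted by ‖f(sᵢ) − f(sⱼ)‖₂.

    Zero weights are legal: identical embeddings mean free movement
    between visually identical tiles.
    """
    g = nx.Graph()
    for i, s in enumerate(grid.spot_ids):
        if grid.in_tissue[i]:
            if s not in emb:
                raise ContractError(f"no embedding for spot {s!r}")
            g.add_node(s)
    for s in g.nodes:
        vs = emb.vector(s)
        for t in grid.neighbors(s):
            if not g.has_edge(s, t):
                w = float(np.linalg.norm(vs - emb.vector(t)))
                g.add_edge(s, t, weight=w)
    return LatticeGraph(graph=g)


def _dijkstra_to(graph: nx.Graph, target: str) -> dict[str, tuple[float, int]]:
    """(cost, hops) of the best path from every reachable node to target.

    Hops participate in the key so that among equal-cost paths the one
    with fewest spots wins.
    """
    dist: dict[str, tuple[float, int]] = {target: (0.0, 0)}
    heap: list[tuple[float, int, str]] = [(0.0, 0, target)]
    done: set[str] = set()
    while heap:
        cost, hops, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        for v in graph.neighbors(u):
            cand = (cost + graph.edges[u, v]["weight"], hops + 1)
            if v not in dist or cand < dist[v]:
                dist[v] = cand
                heapq.heappush(heap, (cand[0], cand[1], v))
    return dist


def shortest_path(graph: LatticeGraph, a: str, b: str) -> TraversalPath:
    """The minimum-total-weight lattice path P* between anchors a and b.

    Dijkstra over (cost, hops) gives optimal distances; the path is
    then reconstructed greedily from ``a``, at each step taking the
    smallest-id neighbor that stays on an optimal path, which yields
    the lexicographically smallest optimal spot sequence.
    """
    g = graph.graph
    for s in (a, b):
        if s not in g:
            raise InvalidArgumentError(f"anchor {s!r} is not a vertex of the graph")
    if a == b:
        return TraversalPath(spots=[a], cost=0.0)
    dist = _dijkstra_to(g, b)
    if a not in dist:
        comp_a = nx.node_connected_component(g, a)
        comp_b = nx.node_connected_component(g, b)
        raise NoPathError(
            f"anchors {a!r} and {b!r} lie in different connected components "
            f"(sizes {len(comp_a)} and {len(comp_b)})"
        )
    spots = [a]
    cost_a, hops_a = dist[a]
    u, remaining = a, dist[a]
    while u != b:
        best: tuple[str, tuple[float, int]] | None = None
        for v in sorted(g.neighbors(u)):
            if v not in dist:
                continue
            w = g.edges[u, v]["weight"]
            through = (w + dist[v][0], 1 + dist[v][1])
            if through == remaining:
                best = (v, dist[v])
                break
        if best is None:  # numerical guard; cannot happen with exact ties
            raise NoPathError(f"path reconstruction failed at {u!r}")
        u, remaining = best
        spots.append(u)
    return TraversalPath(spots=spots, cost=cost_a)
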