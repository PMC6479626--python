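"""Small-world household contact network for word-of-mouth diffusion.

Households are placed on a ring (ordered spatially, so ring neighbours are
geographically close), linked to their k nearest ring neighbours, and each
lattice edge is rewired with probability p (default 0.2) to a uniformly
chosen non-duplicate target, keeping the "home" endpoint fixed.  This is
the Watts-Strogatz construction; it preserves the edge count n*k/2 and
yields high clustering with short path lengths — the structure of local
savings-group communities through which toilet adoption spreads.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = ["AdjacencyNetwork", "build_small_world", "spatial_ring_order", "network_stats"]


@dataclass
class AdjacencyNetwork:
    """Undirected contact network over ``n`` household ids.

    ``edges`` is a set of sorted (u, v) pairs; ``graph`` the networkx view.
    """

    n: int
    graph: nx.Graph

    @property
    def edges(self) -> set[tuple[int, int]]:
        return {(min(u, v), max(u, v)) for u, v in self.graph.edges}

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def to_csr(self) -> tuple[np.ndarray, np.ndarray]:
        """Neighbour lists as (indptr, indices) for fast vectorised lookup."""
        indptr = np.zeros(self.n + 1, dtype=np.int64)
        deg = np.zeros(self.n, dtype=np.int64)
        for u, v in self.graph.edges:
            deg[u] += 1
            deg[v] += 1
        indptr[1:] = np.cumsum(deg)
        indices = np.empty(indptr[-1], dtype=np.int64)
        fill = indptr[:-1].copy()
        for u, v in self.graph.edges:
            indices[fill[u]] = v
            fill[u] += 1
            indices[fill[v]] = u
            fill[v] += 1
        return indptr, indices

    def write_edgelist(self, path) -> None:
        with open(path, "w") as fh:
            for u, v in sorted(self.edges):
                fh.write(f"{u}\t{v}\n")


def spatial_ring_order(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Order households around their centroid so ring neighbours are close.

    Sorts by polar angle about the centroid (radius breaks ties), giving a
    closed tour on which "k nearest neighbours" is geographically sensible.
    """
    cx, cy = np.mean(x), np.mean(y)
    theta = np.arctan2(y - cy, x - cx)
    r = np.hypot(x - cx, y - cy)
    return np.lexsort((r, theta))


def build_small_world(
    n: int,
    k: int = 4,
    p_rewire: float = 0.2,
    seed: int | np.random.Generator | None = None,
    order: np.ndarray | None = None,
) -> AdjacencyNetwork:
    """Build the rewired ring lattice.

    Parameters
    ----------
    n, k
        Node count and (even) initial neighbour count per node.
    p_rewire
        Independent probability that each lattice edge is redirected; the
        home endpoint stays fixed and the new target is uniform over
        non-self, non-duplicate nodes, so the edge count stays n*k/2.
    order
        Optional permutation mapping ring position -> node id (e.g. from
        :func:`spatial_ring_order`); identity if omitted.
    """
    if k % 2 != 0:
        raise ValueError("k must be even")
    if k >= n:
        raise ValueError("k must be smaller than n")
    if not 0.0 <= p_rewire <= 1.0:
        raise ValueError("p_rewire must lie in [0, 1]")
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**31))
    g = nx.watts_strogatz_graph(n, k, p_rewire, seed=seed)
    if order is not None:
        if len(order) != n:
            raise ValueError("order must be a permutation of range(n)")
        g = nx.relabel_nodes(g, {pos: int(node) for pos, node in enumerate(order)})
    return AdjacencyNetwork(n=n, graph=g)


def network_stats(net: AdjacencyNetwork) -> dict:
    """Mean degree, clustering coefficient and mean shortest-path length.

    Path length is computed on the largest connected component when the
    network is disconnected; ``component_fraction`` reports its share.
    """
    g = net.graph
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        raise ValueError("network is empty")
    if nx.is_connected(g):
        comp = g
        frac = 1.0
    else:
        nodes = max(nx.connected_components(g), key=len)
        comp = g.subgraph(nodes)
        frac = len(nodes) / g.number_of_nodes()
    return {
        "mean_degree": 2.0 * g.number_of_edges() / g.number_of_nodes(),
        "clustering_coefficient": nx.average_clustering(g),
        "mean_path_length": nx.average_shortest_path_length(comp),
        "component_fraction": frac,
    }
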