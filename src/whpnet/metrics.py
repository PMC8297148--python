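"""Self-implemented global measures of a weighted organization network.

The measure suite is the classic global toolkit for monitoring network
development: size (nodes, edges), degree measures (average degree, average
weighted degree), distance measures (diameter, average path length by
unweighted breadth-first search), and density/clustering measures (density,
triangle count, average local clustering coefficient).

Conventions:

* Distances are hop counts; edge weights enter only the weighted degree.
  (Weights encode repeated contact, not proximity.)
* ``avg_path_length`` averages over connected pairs only; a disconnected
  graph yields a finite value plus ``is_connected=False``.
* Nodes of degree < 2 have an undefined local clustering coefficient; by
  default they count as 0 and stay in the mean (``exclude_low_degree=True``
  switches to dropping them, the other common convention).
* Full precision is kept internally; :meth:`GlobalMetrics.rounded` renders
  degrees to 1 decimal and density/clustering/path length to 3 decimals for
  report tables.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from typing import Optional

from .network import OneModeNetwork

__all__ = [
    "GlobalMetrics",
    "degree_measures",
    "distance_measures",
    "density",
    "triangle_count",
    "average_clustering",
    "compute_all",
]

#: Canonical row order for report tables.
METRIC_FIELDS = (
    "n_nodes",
    "n_edges",
    "avg_degree",
    "avg_weighted_degree",
    "diameter",
    "avg_path_length",
    "density",
    "avg_clustering",
    "n_triangles",
)


@dataclass(frozen=True)
class GlobalMetrics:
    n_nodes: int
    n_edges: int
    avg_degree: Optional[float]
    avg_weighted_degree: Optional[float]
    diameter: Optional[int]
    avg_path_length: Optional[float]
    density: Optional[float]
    n_triangles: int
    avg_clustering: Optional[float]
    is_connected: bool

    def rounded(self) -> dict[str, object]:
        """Report-table rendering; missing values become the string 'NA'."""

        def r(x, nd):
            return "NA" if x is None else round(x, nd)

        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": r(self.avg_degree, 1),
            "avg_weighted_degree": r(self.avg_weighted_degree, 1),
            "diameter": "NA" if self.diameter is None else self.diameter,
            "avg_path_length": r(self.avg_path_length, 3),
            "density": r(self.density, 3),
            "avg_clustering": r(self.avg_clustering, 3),
            "n_triangles": self.n_triangles,
        }


def degree_measures(g: OneModeNetwork) -> tuple[float, float]:
    """(average degree, average weighted degree) over all nodes."""
    if g.n_nodes == 0:
        raise ValueError("degree measures undefined on an empty graph")
    deg = {n: 0 for n in g.node_groups}
    wdeg = {n: 0.0 for n in g.node_groups}
    for (u, v), w in g.weights.items():
        deg[u] += 1
        deg[v] += 1
        wdeg[u] += w
        wdeg[v] += w
    n = g.n_nodes
    return sum(deg.values()) / n, sum(wdeg.values()) / n


def _bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def distance_measures(
    g: OneModeNetwork,
) -> tuple[Optional[int], Optional[float], bool]:
    """(diameter, average path length, is_connected) by unweighted BFS.

    The diameter is the maximum finite pairwise distance; the average is
    taken over unordered pairs at finite distance.  An edgeless graph has
    neither and returns (None, None, is_connected).
    """
    n = g.n_nodes
    if g.n_edges == 0:
        return None, None, n <= 1
    adj = g.adjacency()
    diameter = 0
    total = 0
    reachable_pairs = 0
    nodes = g.nodes
    for i, u in enumerate(nodes):
        dist = _bfs_distances(adj, u)
        for v in nodes[i + 1:]:
            if v in dist:
                d = dist[v]
                total += d
                reachable_pairs += 1
                if d > diameter:
                    diameter = d
    connected = reachable_pairs == n * (n - 1) // 2
    avg = total / reachable_pairs if reachable_pairs else None
    return (diameter if reachable_pairs else None), avg, connected


def density(g: OneModeNetwork) -> Optional[float]:
    """2E / (N (N-1)); undefined (None) for fewer than two nodes."""
    n = g.n_nodes
    if n < 2:
        return None
    return 2 * g.n_edges / (n * (n - 1))


def triangle_count(g: OneModeNetwork) -> int:
    """Number of distinct 3-cliques, each counted once (weights ignored)."""
    adj = g.adjacency()
    count = 0
    for u, v in g.weights:
        count += len(adj[u] & adj[v])
    # each triangle is seen once per incident edge
    return count // 3


def average_clustering(g: OneModeNetwork, exclude_low_degree: bool = False) -> float:
    """Mean local clustering coefficient.

    c(v) = (# edges among neighbors of v) / C(deg v, 2).  Degree-<2 nodes
    contribute 0 by default; ``exclude_low_degree`` drops them from the
    mean instead (returns nan if nothing remains).
    """
    if g.n_nodes == 0:
        raise ValueError("clustering undefined on an empty graph")
    adj = g.adjacency()
    coeffs = []
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            if not exclude_low_degree:
                coeffs.append(0.0)
            continue
        links = 0
        nbr_list = sorted(nbrs)
        for i, a in enumerate(nbr_list):
            for b in nbr_list[i + 1:]:
                if b in adj[a]:
                    links += 1
        coeffs.append(2 * links / (k * (k - 1)))
    if not coeffs:
        return math.nan
    return sum(coeffs) / len(coeffs)


def compute_all(g: OneModeNetwork,
                clustering_exclude_low_degree: bool = False) -> GlobalMetrics:
    """Assemble the full global-measure suite for one network snapshot.

    Deterministic; measures that are undefined on the given graph (an empty
    or edgeless one) come back as None rather than raising, so trajectory
    rows over early or degenerate windows stay well-formed.
    """
    if g.n_nodes == 0:
        return GlobalMetrics(0, 0, None, None, None, None, None, 0, None, True)
    avg_deg, avg_wdeg = degree_measures(g)
    diam, apl, connected = distance_measures(g)
    return GlobalMetrics(
        n_nodes=g.n_nodes,
        n_edges=g.n_edges,
        avg_degree=avg_deg,
        avg_weighted_degree=avg_wdeg,
        diameter=diam,
        avg_path_length=apl,
        density=density(g),
        n_triangles=triangle_count(g),
        avg_clustering=average_clustering(g, clustering_exclude_low_degree),
        is_connected=connected,
    )
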