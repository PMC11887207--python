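"""Cluster graph, Borůvka MST, vessel path and background removal.

After clustering, each cluster becomes a graph node embedded at
``(x, y) = (distance in pixels from the cluster centroid to the patch
centre, cluster mean HU)``.  Nodes are connected when their clusters share
4-adjacent pixels, with edge weight the Euclidean distance between the two
embedded points (units intentionally mixed: HU differences dominate, which is
part of the method).  The graph is reduced to a minimum spanning tree with
Borůvka's algorithm, the *vessel path* is traced from the cluster under the
patch centre outward in non-increasing mean HU until brightness falls below
``stop_hu``, and every cluster off the path is flattened to the background
cluster's mean -- this is what detaches kissing vessels and other bright
neighbours before the second clustering pass.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .clustering import ClusterLabeling
from .errors import StateError
from .patches import Patch

__all__ = [
    "ClusterGraph",
    "VesselPath",
    "build_graph",
    "boruvka_mst",
    "find_vessel_path",
    "remove_background",
]


@dataclass
class ClusterGraph:
    """Nodes embedded in (centroid-distance, mean-HU) space with adjacency edges."""

    node_ids: np.ndarray            # (k,)
    x: np.ndarray                   # (k,) centroid->centre distance, pixels
    y: np.ndarray                   # (k,) mean HU
    edges: list[tuple[int, int, float]]   # (a, b, weight), a < b
    center_node: int                # cluster containing the patch centre pixel
    mst_edges: list[tuple[int, int, float]] | None = None
    is_forest: bool = False         # True if the adjacency graph was disconnected

    def adjacency(self, mst_only: bool = False) -> dict[int, list[int]]:
        edges = self.mst_edges if mst_only else self.edges
        if edges is None:
            raise StateError("MST not computed")
        adj: dict[int, list[int]] = {int(n): [] for n in self.node_ids}
        for a, b, _ in edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj


@dataclass
class VesselPath:
    """Ordered cluster ids from the vessel interior outward, brightest first."""

    cluster_ids: list[int]
    mean_hus: list[float]

    def __len__(self) -> int:
        return len(self.cluster_ids)

    @property
    def empty(self) -> bool:
        return not self.cluster_ids


def build_graph(labeling: ClusterLabeling,
                center_px: tuple[int, int] = (16, 16)) -> ClusterGraph:
    """Build the cluster adjacency graph in the (distance, mean HU) embedding."""
    if not labeling.has_stats:
        raise StateError("cluster stats must be computed before build_graph")
    labels = labeling.labels
    k = labeling.n_clusters
    center = np.asarray(center_px, dtype=float)
    x = np.linalg.norm(labeling.centroid_px - center, axis=1)
    y = labeling.mean_hu.astype(float)

    pairs = set()
    for a, b in ((labels[:-1, :], labels[1:, :]), (labels[:, :-1], labels[:, 1:])):
        diff = a != b
        pairs.update(zip(np.minimum(a[diff], b[diff]).tolist(),
                         np.maximum(a[diff], b[diff]).tolist()))
    edges = [(a, b, float(np.hypot(x[a] - x[b], y[a] - y[b])))
             for a, b in sorted(pairs)]
    center_node = int(labels[center_px[0], center_px[1]])
    return ClusterGraph(np.arange(k), x, y, edges, center_node)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def boruvka_mst(graph: ClusterGraph) -> ClusterGraph:
    """Reduce the adjacency graph to its minimum spanning tree (Borůvka).

    Each round, every component selects its cheapest outgoing edge (ties
    broken lexicographically by (weight, a, b)) and the selected edges are
    contracted.  On a disconnected graph the result is a minimum spanning
    forest and ``is_forest`` is set.
    """
    n = len(graph.node_ids)
    uf = _UnionFind(n)
    mst: list[tuple[int, int, float]] = []
    n_comp = n
    while n_comp > 1:
        cheapest: dict[int, tuple[float, int, int]] = {}
        for a, b, w in graph.edges:
            ra, rb = uf.find(a), uf.find(b)
            if ra == rb:
                continue
            for root in (ra, rb):
                cand = (w, a, b)
                if root not in cheapest or cand < cheapest[root]:
                    cheapest[root] = cand
        if not cheapest:
            break  # disconnected: no edge leaves any remaining component
        for w, a, b in sorted(set(cheapest.values())):
            if uf.union(a, b):
                mst.append((a, b, w))
                n_comp -= 1
    return replace(graph, mst_edges=mst, is_forest=n_comp > 1)


def find_vessel_path(graph: ClusterGraph, stop_hu: float = 100.0) -> VesselPath:
    """Trace the vessel path over the MST in non-increasing mean HU.

    The start node is the cluster containing the patch centre if its mean HU
    is at least ``stop_hu``; otherwise the eligible node nearest the centre
    (smallest embedded x, brightest on ties).  From there, MST neighbours of
    the path are admitted brightest-first, but only while their mean HU does
    not exceed the previously admitted cluster's and stays at or above
    ``stop_hu`` -- so a bright structure beyond a dark gap can never re-enter
    the path.  If no node reaches ``stop_hu`` the path is empty, which signals
    the fallback threshold downstream.
    """
    if graph.mst_edges is None:
        raise StateError("MST must be computed before the vessel path search")
    y = graph.y
    eligible = [int(i) for i in graph.node_ids if y[i] >= stop_hu]
    if not eligible:
        return VesselPath([], [])
    if y[graph.center_node] >= stop_hu:
        start = graph.center_node
    else:
        start = min(eligible, key=lambda i: (graph.x[i], -y[i]))

    adj = graph.adjacency(mst_only=True)
    visited = {start}
    path = [start]
    frontier = set(adj[start])
    while True:
        last_hu = y[path[-1]]
        candidates = [i for i in frontier
                      if i not in visited and stop_hu <= y[i] <= last_hu]
        if not candidates:
            break
        nxt = max(candidates, key=lambda i: (y[i], -i))
        visited.add(nxt)
        path.append(nxt)
        frontier.discard(nxt)
        frontier.update(j for j in adj[nxt] if j not in visited)
    return VesselPath(path, [float(y[i]) for i in path])


def remove_background(patch: Patch, labeling: ClusterLabeling,
                      path: VesselPath) -> tuple[Patch, bool]:
    """Flatten every off-path cluster to the background cluster's mean HU.

    The background cluster is the one with the lowest mean HU.  Pixels of
    path clusters are untouched.  Returns ``(patch, applied)``; an empty path
    leaves the patch unmodified with ``applied=False``.
    """
    if not labeling.has_stats:
        raise StateError("cluster stats required for background removal")
    if path.empty:
        return patch, False
    fill = float(labeling.mean_hu.min())
    keep = np.isin(labeling.labels, path.cluster_ids)
    values = np.where(keep, patch.values, fill)
    return replace(patch, values=values), True
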