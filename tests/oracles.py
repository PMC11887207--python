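"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive recomputation, pairwise
scans) and shares no code with the package internals.
"""

from __future__ import annotations

import numpy as np


def greedy_ward_partition(values: np.ndarray, n_clusters: int) -> set[frozenset]:
    """Greedy Ward agglomeration with a 4-connectivity constraint.

    Recomputes the Ward merge cost of every adjacent cluster pair from
    scratch at every step; ties broken by the lexicographically smallest
    (cost, smaller-id, larger-id).  Returns the partition of flat pixel
    indices as a set of frozensets.
    """
    h, w = values.shape
    flat = values.ravel()
    clusters: dict[int, list[int]] = {i: [i] for i in range(h * w)}

    def pixel_neighbors(p: int) -> list[int]:
        i, j = divmod(p, w)
        out = []
        if i > 0:
            out.append(p - w)
        if i < h - 1:
            out.append(p + w)
        if j > 0:
            out.append(p - 1)
        if j < w - 1:
            out.append(p + 1)
        return out

    adj = {i: set(pixel_neighbors(i)) for i in range(h * w)}
    next_id = h * w
    while len(clusters) > n_clusters:
        best = None
        for a in clusters:
            for b in adj[a]:
                if b <= a:
                    continue
                na, nb = len(clusters[a]), len(clusters[b])
                ma = flat[clusters[a]].mean()
                mb = flat[clusters[b]].mean()
                cost = na * nb / (na + nb) * (ma - mb) ** 2
                key = (cost, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        clusters[next_id] = clusters.pop(a) + clusters.pop(b)
        adj[next_id] = (adj.pop(a) | adj.pop(b)) - {a, b}
        for c in adj:
            if c != next_id and (a in adj[c] or b in adj[c]):
                adj[c] -= {a, b}
                adj[c].add(next_id)
        next_id += 1
    return {frozenset(members) for members in clusters.values()}


def labels_to_partition(labels: np.ndarray) -> set[frozenset]:
    flat = labels.ravel()
    return {frozenset(np.flatnonzero(flat == l).tolist())
            for l in np.unique(flat)}


def kruskal_mst_weight(n_nodes: int, edges: list[tuple[int, int, float]]
                       ) -> list[float]:
    """Sorted MST edge weights by Kruskal's algorithm (sort + union-find)."""
    parent = list(range(n_nodes))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    weights = []
    for a, b, w in sorted(edges, key=lambda e: e[2]):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
            weights.append(w)
            if len(weights) == n_nodes - 1:
                break
    return sorted(weights)


def majority_median(mask: np.ndarray, edge: int) -> np.ndarray:
    """Brute-force binary median filter with a cubic kernel (edge-replicated
    padding, matching scipy's 'reflect'-free nearest behaviour)."""
    r = edge // 2
    padded = np.pad(mask.astype(int), r, mode="edge")
    out = np.zeros_like(mask, dtype=bool)
    half = edge ** 3 // 2
    for idx in np.ndindex(mask.shape):
        block = padded[idx[0]:idx[0] + edge, idx[1]:idx[1] + edge,
                       idx[2]:idx[2] + edge]
        out[idx] = block.sum() > half
    return out


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Positive voxels with at least one 6-neighbour outside the mask."""
    out = np.zeros_like(mask, dtype=bool)
    padded = np.pad(mask, 1, mode="constant")
    core = padded[1:-1, 1:-1, 1:-1]
    neigh_all = np.ones_like(core, dtype=bool)
    for axis in range(3):
        for shift in (-1, 1):
            neigh_all &= np.roll(padded, shift, axis=axis)[1:-1, 1:-1, 1:-1]
    out = core & ~neigh_all
    return out


def pairwise_surface_distances(a: np.ndarray, b: np.ndarray,
                               spacing: float) -> tuple[float, float]:
    """Hausdorff and mean surface distance by exhaustive pairwise scan."""
    pa = np.argwhere(boundary_voxels(a)) * spacing
    pb = np.argwhere(boundary_voxels(b)) * spacing
    d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
    d_ab = d.min(axis=1)
    d_ba = d.min(axis=0)
    hausdorff = max(d_ab.max(), d_ba.max())
    msd = (d_ab.mean() + d_ba.mean()) / 2
    return float(hausdorff), float(msd)


def random_connected_graph(rng: np.random.Generator, max_nodes: int = 20
                           ) -> tuple[int, list[tuple[int, int, float]]]:
    """A random connected weighted graph: random spanning tree + extra edges."""
    n = int(rng.integers(2, max_nodes + 1))
    edges = []
    seen = set()
    for v in range(1, n):
        u = int(rng.integers(0, v))
        edges.append((u, v, float(rng.uniform(0.1, 10))))
        seen.add((u, v))
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        u, v = sorted(rng.choice(n, 2, replace=False).tolist())
        if (u, v) in seen:
            continue
        seen.add((u, v))
        edges.append((u, v, float(rng.uniform(0.1, 10))))
    return n, edges
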