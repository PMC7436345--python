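"""Independent brute-force reference implementations for the centrality tests.

These deliberately avoid the package's code paths and networkx's centrality
routines: betweenness and closeness come from explicit BFS distance/path
counting, eigenvector centrality from a dense eigendecomposition, and
LAC/NC from explicit neighborhood and triangle enumeration over adjacency
sets.
"""

from collections import deque

import numpy as np


def _bfs_counts(adj: dict, source):
    """Distances and shortest-path counts from one source (unit weights)."""
    dist = {source: 0}
    sigma = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for w in adj[u]:
            if w not in dist:
                dist[w] = dist[u] + 1
                sigma[w] = 0
                queue.append(w)
            if dist[w] == dist[u] + 1:
                sigma[w] += sigma[u]
    return dist, sigma


def brute_betweenness(adj: dict) -> dict:
    """Unnormalized betweenness over unordered pairs via the pair-count identity
    sigma_st(v) = sigma_sv * sigma_vt when d(s,v) + d(v,t) = d(s,t)."""
    nodes = list(adj)
    dist = {}
    sigma = {}
    for s in nodes:
        dist[s], sigma[s] = _bfs_counts(adj, s)
    bc = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            if t not in dist[s]:
                continue
            d_st = dist[s][t]
            for v in nodes:
                if v in (s, t) or v not in dist[s] or t not in dist[v]:
                    continue
                if dist[s][v] + dist[v][t] == d_st:
                    bc[v] += sigma[s][v] * sigma[v][t] / sigma[s][t]
    return bc


def brute_closeness(adj: dict) -> dict:
    """Component-local closeness: (|C|-1) / sum of distances inside C."""
    out = {}
    for v in adj:
        dist, _ = _bfs_counts(adj, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def brute_eigenvector(adj: dict) -> dict:
    """Dominant eigenvector of the dense adjacency matrix, |.|, L2-normalized."""
    nodes = sorted(adj)
    n = len(nodes)
    if n == 0:
        return {}
    a = np.zeros((n, n))
    index = {v: i for i, v in enumerate(nodes)}
    for v in nodes:
        for u in adj[v]:
            a[index[v], index[u]] = 1.0
    if not a.any():
        return {v: 0.0 for v in nodes}
    vals, vecs = np.linalg.eigh(a)
    vec = np.abs(vecs[:, np.argmax(vals)])
    vec /= np.linalg.norm(vec)
    return {v: float(vec[index[v]]) for v in nodes}


def brute_lac(adj: dict) -> dict:
    """Mean within-neighborhood degree of each node's neighbors."""
    out = {}
    for v, nbrs in adj.items():
        if not nbrs:
            out[v] = 0.0
            continue
        total = 0
        for u in nbrs:
            total += sum(1 for w in adj[u] if w in nbrs)
        out[v] = total / len(nbrs)
    return out


def brute_nc(adj: dict, plus_one: bool = False) -> dict:
    """Sum of edge clustering coefficients z / min(d_v - 1, d_u - 1)."""
    out = {}
    for v, nbrs in adj.items():
        total = 0.0
        for u in nbrs:
            z = sum(1 for w in adj[v] if w in adj[u])
            denom = min(len(nbrs) - 1, len(adj[u]) - 1)
            if denom > 0:
                total += ((z + 1) if plus_one else z) / denom
        out[v] = total
    return out


def adj_from_graph(graph) -> dict:
    return {v: set(graph.neighbors(v)) for v in graph.nodes()}
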