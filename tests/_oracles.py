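"""Independent brute-force oracles for the graph measures.

These deliberately avoid the package's algorithms: betweenness is computed by
explicitly enumerating every shortest path (recursive backtracking over a BFS
distance map), coreness by literal iterative pruning at each k, closeness by a
plain distance dictionary.  Only usable at small n.
"""

from __future__ import annotations

import itertools
from collections import deque


def bfs_distances(adj: dict[str, set[str]], s: str) -> dict[str, int]:
    dist = {s: 0}
    q = deque([s])
    while q:
        v = q.popleft()
        for w in adj[v]:
            if w not in dist:
                dist[w] = dist[v] + 1
                q.append(w)
    return dist


def all_shortest_paths(adj: dict[str, set[str]], s: str, t: str) -> list[list[str]]:
    """Every shortest s-t path, by backtracking from t along the BFS distances."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    paths: list[list[str]] = []

    def back(v: str, suffix: list[str]) -> None:
        if v == s:
            paths.append([s] + suffix)
            return
        for u in adj[v]:
            if u in dist and dist[u] == dist[v] - 1:
                back(u, [v] + suffix)

    back(t, [])
    return paths


def brute_node_betweenness(adj: dict[str, set[str]]) -> dict[str, float]:
    nodes = sorted(adj)
    bc = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for p in paths:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def brute_edge_betweenness(adj: dict[str, set[str]]) -> dict[tuple[str, str], float]:
    nodes = sorted(adj)
    eb = {
        tuple(sorted((u, v))): 0.0
        for u in nodes
        for v in adj[u]
        if u < v
    }
    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for p in paths:
            for u, v in zip(p, p[1:]):
                eb[tuple(sorted((u, v)))] += 1.0 / len(paths)
    return eb


def brute_closeness(adj: dict[str, set[str]]) -> dict[str, float]:
    out = {}
    for v in sorted(adj):
        dist = bfs_distances(adj, v)
        far = sum(dist.values())
        out[v] = (len(dist) - 1) / far if far else 0.0
    return out


def prune_at_k(adj: dict[str, set[str]], k: int) -> set[str]:
    """Node set of the k-core by literal repeated deletion."""
    keep = set(adj)
    while True:
        drop = {v for v in keep if len(adj[v] & keep) < k}
        if not drop:
            return keep
        keep -= drop


def brute_coreness(adj: dict[str, set[str]]) -> dict[str, int]:
    core = dict.fromkeys(adj, 0)
    k = 1
    while True:
        members = prune_at_k(adj, k)
        if not members:
            return core
        for v in members:
            core[v] = k
        k += 1


def pairwise_distance_sum(adj: dict[str, set[str]]) -> float:
    """Sum of shortest-path distances over all connected unordered pairs."""
    total = 0
    for s in sorted(adj):
        d = bfs_distances(adj, s)
        total += sum(d.values())
    return total / 2.0
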