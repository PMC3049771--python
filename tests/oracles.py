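"""Independent brute-force reference implementations used as test oracles.

These deliberately avoid networkx/scipy code paths: plain-dict BFS,
exhaustive shortest-path enumeration, neighbour-pair counting, union-find,
ECDF sweeps and hypergeometric summation with math.comb.
"""

from __future__ import annotations

from math import comb, exp


def adjacency(nodes, edges) -> dict:
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    return adj


def brute_degree(adj) -> dict:
    return {v: len(nbrs) for v, nbrs in adj.items()}


def brute_clustering(adj) -> dict:
    out = {}
    for v, nbrs in adj.items():
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        nl = sorted(nbrs)
        e_n = sum(
            1 for i, a in enumerate(nl) for b in nl[i + 1 :] if b in adj[a]
        )
        out[v] = e_n / (k * (k - 1) / 2)
    return out


def brute_components(adj) -> int:
    parent = {v: v for v in adj}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, nbrs in adj.items():
        for v in nbrs:
            ru, rv = find(u), find(v)
            if ru != rv:
                parent[ru] = rv
    return len({find(v) for v in adj})


def _bfs_dist(adj, src) -> dict:
    dist = {src: 0}
    frontier = [src]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    nxt.append(w)
        frontier = nxt
    return dist


def all_shortest_paths(adj, s, t) -> list[list]:
    """Every shortest s-t path, by DFS along strictly distance-decreasing
    edges (exhaustive enumeration)."""
    dist = _bfs_dist(adj, s)
    if t not in dist:
        return []
    paths: list[list] = []

    def rec(v, suffix):
        if v == s:
            paths.append([s] + suffix)
            return
        for u in adj[v]:
            if dist.get(u, -1) == dist[v] - 1:
                rec(u, [v] + suffix)

    rec(t, [])
    return paths


def brute_rel_betweenness(adj) -> dict:
    """rC_B via exhaustive shortest-path enumeration over unordered pairs,
    normalised by (n-1)(n-2)/2; all zeros when n < 3."""
    nodes = sorted(adj)
    n = len(nodes)
    cb = {v: 0.0 for v in nodes}
    if n >= 3:
        for i, s in enumerate(nodes):
            for t in nodes[i + 1 :]:
                paths = all_shortest_paths(adj, s, t)
                if not paths:
                    continue
                for p in paths:
                    for v in p[1:-1]:
                        cb[v] += 1.0 / len(paths)
        norm = (n - 1) * (n - 2) / 2
        return {v: cb[v] / norm for v in nodes}
    return cb


def ecdf(sample, x) -> float:
    return sum(1 for s in sample if s <= x) / len(sample)


def brute_ks_dplus(observed, null) -> float:
    """sup_x [F_null(x) - F_obs(x)] by sweeping every sample point."""
    return max(
        (ecdf(null, x) - ecdf(observed, x)) for x in set(observed) | set(null)
    )


def brute_ks_d(a, b) -> float:
    """Two-sided sup |F_a - F_b| by exhaustive sweep."""
    return max(abs(ecdf(a, x) - ecdf(b, x)) for x in set(a) | set(b))


def ks_greater_p(observed, null) -> float:
    d = brute_ks_dplus(observed, null)
    if d <= 0:
        return 1.0
    m = len(observed) * len(null) / (len(observed) + len(null))
    return min(1.0, exp(-2 * m * d * d))


def hypergeom_upper_tail(k, M, K, n) -> float:
    """P[X >= k] for X ~ Hypergeom(pop M, successes K, draws n)."""
    return sum(
        comb(K, j) * comb(M - K, n - j) for j in range(k, min(K, n) + 1)
    ) / comb(M, n)
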