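"""Independent brute-force oracles for the topological centrality methods.

Everything here is deliberately written against different primitives than
the package implementation: Floyd-Warshall distance matrices, explicit
shortest-path enumeration, hand-rolled Bron-Kerbosch, and a second
Monte-Carlo percolation routine based on scipy's sparse component labeling.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

INF = float("inf")


def adjacency(nodes, edges):
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    adj = [[False] * n for _ in range(n)]
    for a, b in edges:
        adj[idx[a]][idx[b]] = True
        adj[idx[b]][idx[a]] = True
    return adj, idx


def floyd_warshall(adj):
    n = len(adj)
    dist = [[0 if i == j else (1 if adj[i][j] else INF) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            dik = dist[i][k]
            if dik == INF:
                continue
            for j in range(n):
                alt = dik + dist[k][j]
                if alt < dist[i][j]:
                    dist[i][j] = alt
    return dist


def path_counts(adj, dist):
    """sigma[s][t]: number of shortest s-t paths, by DP over distance."""
    n = len(adj)
    sigma = [[0] * n for _ in range(n)]
    for s in range(n):
        sigma[s][s] = 1
        order = sorted((d, t) for t, d in enumerate(dist[s]) if d != INF)
        for d, t in order:
            if t == s:
                continue
            sigma[s][t] = sum(
                sigma[s][w] for w in range(n) if adj[w][t] and dist[s][w] == d - 1
            )
    return sigma


def enumerate_shortest_paths(adj, dist, s, t):
    """All shortest s-t paths as node tuples (explicit backtracking)."""
    if dist[s][t] == INF:
        return []
    paths = []

    def extend(path):
        u = path[-1]
        if u == t:
            paths.append(tuple(path))
            return
        for w in range(len(adj)):
            if adj[u][w] and dist[s][w] == dist[s][u] + 1 and dist[w][t] == dist[s][t] - dist[s][w]:
                extend(path + [w])

    extend([s])
    return paths


def brute_degree(nodes, edges):
    adj, idx = adjacency(nodes, edges)
    return {v: float(sum(adj[idx[v]])) for v in nodes}


def brute_betweenness(nodes, edges):
    adj, idx = adjacency(nodes, edges)
    dist = floyd_warshall(adj)
    n = len(nodes)
    out = {v: 0.0 for v in nodes}
    for s in range(n):
        for t in range(s + 1, n):
            paths = enumerate_shortest_paths(adj, dist, s, t)
            if not paths:
                continue
            total = len(paths)
            for v in nodes:
                vi = idx[v]
                if vi in (s, t):
                    continue
                through = sum(1 for p in paths if vi in p)
                out[v] += through / total
    return out


def brute_stress(nodes, edges):
    adj, idx = adjacency(nodes, edges)
    dist = floyd_warshall(adj)
    n = len(nodes)
    out = {v: 0.0 for v in nodes}
    for s in range(n):
        for t in range(s + 1, n):
            for p in enumerate_shortest_paths(adj, dist, s, t):
                for vi in p[1:-1]:
                    out[nodes[vi]] += 1.0
    return out


def brute_closeness(nodes, edges):
    adj, idx = adjacency(nodes, edges)
    dist = floyd_warshall(adj)
    return {
        v: sum(1.0 / dist[idx[v]][j] for j in range(len(nodes)) if j != idx[v] and dist[idx[v]][j] != INF)
        for v in nodes
    }


def brute_eccentricity(nodes, edges):
    adj, idx = adjacency(nodes, edges)
    dist = floyd_warshall(adj)
    out = {}
    for v in nodes:
        finite = [d for d in dist[idx[v]] if d != INF]
        ecc = max(finite)
        out[v] = 1.0 / ecc if ecc > 0 else 0.0
    return out


def brute_radiality(nodes, edges):
    adj, idx = adjacency(nodes, edges)
    dist = floyd_warshall(adj)
    out = {}
    for v in nodes:
        vi = idx[v]
        comp = [j for j in range(len(nodes)) if dist[vi][j] != INF]
        nc = len(comp)
        if nc == 1:
            out[v] = 0.0
            continue
        diam = max(dist[i][j] for i in comp for j in comp if dist[i][j] != INF)
        out[v] = sum(diam + 1 - dist[vi][j] for j in comp if j != vi) / (nc - 1)
    return out


def brute_clustering(nodes, edges):
    adj, idx = adjacency(nodes, edges)
    n = len(nodes)
    out = {}
    for v in nodes:
        vi = idx[v]
        nbrs = [j for j in range(n) if adj[vi][j]]
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        links = sum(
            1 for i in range(k) for j in range(i + 1, k) if adj[nbrs[i]][nbrs[j]]
        )
        out[v] = 2.0 * links / (k * (k - 1))
    return out


def _neighbor_components(adj, vi):
    nbrs = [j for j in range(len(adj)) if adj[vi][j]]
    unvisited = set(nbrs)
    comps = []
    while unvisited:
        stack = [unvisited.pop()]
        comp = {stack[0]}
        while stack:
            u = stack.pop()
            for w in list(unvisited):
                if adj[u][w]:
                    unvisited.discard(w)
                    comp.add(w)
                    stack.append(w)
        comps.append(comp)
    return comps


def brute_mnc(nodes, edges):
    adj, idx = adjacency(nodes, edges)
    out = {}
    for v in nodes:
        comps = _neighbor_components(adj, idx[v])
        out[v] = float(max((len(c) for c in comps), default=0))
    return out


def brute_dmnc(nodes, edges, exponent: float = 1.7):
    adj, idx = adjacency(nodes, edges)
    out = {}
    for v in nodes:
        comps = _neighbor_components(adj, idx[v])
        if not comps:
            out[v] = 0.0
            continue

        def n_internal(c):
            cl = sorted(c)
            return sum(
                1
                for i in range(len(cl))
                for j in range(i + 1, len(cl))
                if adj[cl[i]][cl[j]]
            )

        comp = max(
            comps,
            key=lambda c: (len(c), n_internal(c), tuple(nodes[i] for i in sorted(c))),
        )
        if len(comp) <= 1:
            out[v] = 0.0
            continue
        comp_list = sorted(comp)
        e = sum(
            1
            for i in range(len(comp_list))
            for j in range(i + 1, len(comp_list))
            if adj[comp_list[i]][comp_list[j]]
        )
        out[v] = e / len(comp) ** exponent
    return out


def bron_kerbosch(adj):
    """All maximal cliques, basic Bron-Kerbosch without pivoting."""
    n = len(adj)
    cliques = []

    def expand(r, p, x):
        if not p and not x:
            cliques.append(frozenset(r))
            return
        for v in sorted(p):
            nv = {w for w in range(n) if adj[v][w]}
            expand(r | {v}, p & nv, x & nv)
            p = p - {v}
            x = x | {v}

    expand(set(), set(range(n)), set())
    return cliques


def brute_mcc(nodes, edges):
    adj, idx = adjacency(nodes, edges)
    cliques = bron_kerbosch(adj)
    out = {}
    for v in nodes:
        vi = idx[v]
        nbrs = [j for j in range(len(nodes)) if adj[vi][j]]
        has_internal = any(
            adj[nbrs[i]][nbrs[j]] for i in range(len(nbrs)) for j in range(i + 1, len(nbrs))
        )
        if not has_internal:
            out[v] = float(len(nbrs))
        else:
            out[v] = float(
                sum(math.factorial(len(c) - 1) for c in cliques if vi in c)
            )
    return out


def brute_bottleneck(nodes, edges):
    """Canonical BFS tree per root (sorted-neighbor FIFO order), counting
    nodes whose subtree exceeds a quarter of the tree."""
    adj, idx = adjacency(nodes, edges)
    order = {v: i for i, v in enumerate(sorted(nodes))}
    out = {v: 0.0 for v in nodes}
    for s in sorted(nodes):
        si = idx[s]
        parent = {si: None}
        frontier = [si]
        seq = [si]
        while frontier:
            nxt = []
            for u in frontier:
                for w in sorted(
                    (j for j in range(len(nodes)) if adj[u][j]),
                    key=lambda j: order[nodes[j]],
                ):
                    if w not in parent:
                        parent[w] = u
                        nxt.append(w)
                        seq.append(w)
            frontier = nxt
        size = {v: 1 for v in parent}
        for v in reversed(seq):
            if parent[v] is not None:
                size[parent[v]] += size[v]
        tree_n = len(parent)
        for v in parent:
            if v != si and size[v] > tree_n / 4.0:
                out[nodes[v]] += 1.0
    return out


def mc_epc(nodes, edges, confidences, seed, n_reps=1000):
    """Second Monte-Carlo EPC: sparse-matrix component labeling.

    Returns (mean per node, variance of per-replicate sizes per node).
    """
    idx = {v: i for i, v in enumerate(nodes)}
    n = len(nodes)
    rows = np.array([idx[a] for a, _ in edges], dtype=int)
    cols = np.array([idx[b] for _, b in edges], dtype=int)
    probs = np.asarray(confidences, dtype=float) / 1000.0
    rng = np.random.default_rng(seed)
    sizes = np.zeros((n_reps, n))
    for r in range(n_reps):
        # binomial draw: distinct RNG stream path from uniform thresholding
        keep = rng.binomial(1, probs).astype(bool) if len(probs) else np.empty(0, bool)
        data = np.ones(int(keep.sum()))
        m = csr_matrix((data, (rows[keep], cols[keep])), shape=(n, n))
        _, labels = connected_components(m, directed=False)
        counts = np.bincount(labels, minlength=labels.max() + 1)
        sizes[r] = counts[labels]
    return (
        {v: sizes[:, idx[v]].mean() for v in nodes},
        {v: sizes[:, idx[v]].var(ddof=1) for v in nodes},
    )


BRUTE = {
    "Degree": brute_degree,
    "Betweenness": brute_betweenness,
    "Stress": brute_stress,
    "Closeness": brute_closeness,
    "EcCentricity": brute_eccentricity,
    "Radiality": brute_radiality,
    "ClusteringCoefficient": brute_clustering,
    "MNC": brute_mnc,
    "DMNC": brute_dmnc,
    "MCC": brute_mcc,
    "Bottleneck": brute_bottleneck,
}
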