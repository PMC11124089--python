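"""PPI-network biomarker nomination.

Candidate genes are preselected by |Spearman| correlation with a drug's
imputed response, an induced subnetwork is built from a STRING-style edge
table at a confidence floor, each node is scored by 12 topological
centrality methods, and consensus hubs (genes in the top-k list of at
least ``min_methods`` methods) are filtered by a signed Spearman test
against measured response.

Centrality definitions follow the classical hub-detection formulations:

- Degree, Betweenness (unnormalized, unordered pairs), Stress (raw
  shortest-path counts through the node), Closeness (harmonic: sum of
  reciprocal distances), EcCentricity (reciprocal eccentricity within the
  component), Radiality, ClusteringCoefficient, MNC (size of the largest
  connected component of the open neighborhood), DMNC (|E|/|V|^1.7 of that
  component), MCC (factorial-weighted maximal-clique sum, falling back to
  degree for edgeless neighborhoods), Bottleneck (canonical BFS-tree
  descendant counts exceeding |tree|/4), and EPC (Monte-Carlo expected
  component size under independent edge retention).
"""

from __future__ import annotations

import logging
import math
import warnings
from collections import deque

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "METHODS",
    "preselect_correlated_genes",
    "build_ppi_subnetwork",
    "centrality",
    "centrality_table",
    "consensus_hubs",
    "spearman_biomarker_filter",
    "stratum_response_test",
]

METHODS = (
    "Betweenness",
    "Bottleneck",
    "Closeness",
    "ClusteringCoefficient",
    "Degree",
    "DMNC",
    "EcCentricity",
    "EPC",
    "MCC",
    "MNC",
    "Radiality",
    "Stress",
)


def preselect_correlated_genes(
    expr: pd.DataFrame,
    imputed_drug: pd.Series,
    threshold: float = 0.4,
) -> list[str]:
    """Genes with |Spearman rho| >= threshold against the drug's imputed response."""
    shared = [s for s in expr.columns if s in imputed_drug.index]
    if len(shared) < 5:
        raise ValueError("need at least 5 shared samples")
    sub = expr[shared]
    y = imputed_drug.loc[shared].to_numpy(float)
    const = sub.std(axis=1, ddof=0) == 0
    if const.any():
        warnings.warn(
            f"excluding {int(const.sum())} constant genes (correlation undefined)",
            stacklevel=2,
        )
        sub = sub.loc[~const]
    # vectorized Spearman: Pearson on ranks
    rx = stats.rankdata(sub.to_numpy(float), axis=1)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    rho = (rx @ ry) / denom
    return [g for g, r in zip(sub.index, rho) if abs(r) >= threshold]


def build_ppi_subnetwork(
    edges: pd.DataFrame,
    genes: list[str],
    min_conf: int = 700,
) -> nx.Graph:
    """Induced subgraph on the supplied genes only (no added interactors),
    keeping edges with confidence >= ``min_conf``. Isolated supplied genes
    stay as nodes."""
    if not genes:
        raise ValueError("gene list is empty")
    gene_set = set(genes)
    g = nx.Graph()
    g.add_nodes_from(sorted(gene_set))
    sub = edges[
        edges["protein1"].isin(gene_set)
        & edges["protein2"].isin(gene_set)
        & (edges["combined_score"] >= min_conf)
    ]
    for a, b, score in sub[["protein1", "protein2", "combined_score"]].itertuples(index=False):
        if a == b:
            continue
        if g.has_edge(a, b):
            g[a][b]["confidence"] = max(g[a][b]["confidence"], int(score))
        else:
            g.add_edge(a, b, confidence=int(score))
    return g


# ---------------------------------------------------------------------------
# individual centrality methods
# ---------------------------------------------------------------------------

def _shortest_path_counts(g: nx.Graph):
    """All-pairs BFS distances and shortest-path counts (dicts keyed by node)."""
    dist: dict = {}
    sigma: dict = {}
    for s in g:
        d = {s: 0}
        sig = {s: 1.0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for w in g[u]:
                if w not in d:
                    d[w] = d[u] + 1
                    sig[w] = 0.0
                    queue.append(w)
                if d[w] == d[u] + 1:
                    sig[w] += sig[u]
        dist[s] = d
        sigma[s] = sig
    return dist, sigma


def _stress(g: nx.Graph) -> dict:
    dist, sigma = _shortest_path_counts(g)
    nodes = sorted(g)
    out = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        ds, sig_s = dist[s], sigma[s]
        for t in nodes[i + 1 :]:
            if t not in ds:
                continue
            dt, sig_t = dist[t], sigma[t]
            d_st = ds[t]
            for v in ds:
                if v == s or v == t:
                    continue
                if v in dt and ds[v] + dt[v] == d_st:
                    out[v] += sig_s[v] * sig_t[v]
    return out


def _eccentricity_centrality(g: nx.Graph) -> dict:
    out = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if len(comp) == 1:
            out[next(iter(comp))] = 0.0
            continue
        ecc = nx.eccentricity(sub)
        for v, e in ecc.items():
            out[v] = 1.0 / e
    return out


def _radiality(g: nx.Graph) -> dict:
    out = {}
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        nc = len(comp)
        if nc == 1:
            out[next(iter(comp))] = 0.0
            continue
        lengths = dict(nx.all_pairs_shortest_path_length(sub))
        diam = max(max(d.values()) for d in lengths.values())
        for v in comp:
            out[v] = sum(
                (diam + 1 - d) for w, d in lengths[v].items() if w != v
            ) / (nc - 1)
    return out


def _neighborhood_component(g: nx.Graph, v) -> nx.Graph:
    """Largest connected component of the induced subgraph on N(v)."""
    nbrs = list(g[v])
    if not nbrs:
        return nx.Graph()
    sub = g.subgraph(nbrs)
    # ties in component size broken by internal edge count, then node ids
    comp = max(
        nx.connected_components(sub),
        key=lambda c: (len(c), sub.subgraph(c).number_of_edges(), tuple(sorted(c))),
    )
    return sub.subgraph(comp)


def _mnc(g: nx.Graph) -> dict:
    return {v: float(len(_neighborhood_component(g, v))) for v in g}


def _dmnc(g: nx.Graph, exponent: float = 1.7) -> dict:
    out = {}
    for v in g:
        m = _neighborhood_component(g, v)
        nv = m.number_of_nodes()
        out[v] = 0.0 if nv <= 1 else m.number_of_edges() / nv**exponent
    return out


def _mcc(g: nx.Graph) -> dict:
    out = {v: 0.0 for v in g}
    edgeless = {}
    for v in g:
        nbrs = list(g[v])
        edgeless[v] = not any(g.has_edge(a, b) for i, a in enumerate(nbrs) for b in nbrs[i + 1 :])
    cliques_by_node: dict = {v: [] for v in g}
    for clique in nx.find_cliques(g):
        for v in clique:
            cliques_by_node[v].append(len(clique))
    for v in g:
        if edgeless[v]:
            out[v] = float(g.degree(v))
        else:
            out[v] = float(sum(math.factorial(c - 1) for c in cliques_by_node[v]))
    return out


def _canonical_bfs_tree(g: nx.Graph, root):
    """BFS tree with neighbors visited in sorted order; returns parent map."""
    parent = {root: None}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for w in sorted(g[u]):
            if w not in parent:
                parent[w] = u
                queue.append(w)
    return parent


def _bottleneck(g: nx.Graph) -> dict:
    out = {v: 0.0 for v in g}
    for s in sorted(g):
        parent = _canonical_bfs_tree(g, s)
        tree_size = len(parent)
        counts = {v: 1 for v in parent}
        # accumulate descendant counts leaf-up (depth via parent chains)
        depth = {}
        for v in parent:
            d = 0
            u = v
            while parent[u] is not None:
                u = parent[u]
                d += 1
            depth[v] = d
        for v in sorted(parent, key=lambda x: -depth[x]):
            p = parent[v]
            if p is not None:
                counts[p] += counts[v]
        for v in parent:
            if v != s and counts[v] > tree_size / 4.0:
                out[v] += 1.0
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))
        self.size = [1] * n

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]


def _epc(g: nx.Graph, seed: int | None, n_reps: int = 1000) -> dict:
    """Expected component size under independent edge retention with
    probability confidence/1000 (0.5 when unweighted)."""
    nodes = sorted(g)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [
        (index[a], index[b], g[a][b].get("confidence", 500) / 1000.0)
        for a, b in g.edges()
    ]
    rng = np.random.default_rng(seed)
    totals = np.zeros(len(nodes))
    probs = np.array([p for _, _, p in edges])
    for _ in range(n_reps):
        keep = rng.random(len(edges)) < probs if len(edges) else np.empty(0, bool)
        uf = _UnionFind(len(nodes))
        for (a, b, _), k in zip(edges, keep):
            if k:
                uf.union(a, b)
        sizes = np.array([uf.size[uf.find(i)] for i in range(len(nodes))], float)
        totals += sizes
    return {v: totals[index[v]] / n_reps for v in nodes}


def centrality(
    graph: nx.Graph,
    method: str,
    seed: int | None = None,
    n_reps: int = 1000,
) -> dict:
    """Per-node score for one of the 12 topological methods."""
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if method == "Degree":
        return {v: float(d) for v, d in graph.degree()}
    if method == "Betweenness":
        return nx.betweenness_centrality(graph, normalized=False)
    if method == "Stress":
        return _stress(graph)
    if method == "Closeness":
        return {v: float(c) for v, c in nx.harmonic_centrality(graph).items()}
    if method == "EcCentricity":
        return _eccentricity_centrality(graph)
    if method == "Radiality":
        return _radiality(graph)
    if method == "ClusteringCoefficient":
        return {v: float(c) for v, c in nx.clustering(graph).items()}
    if method == "MNC":
        return _mnc(graph)
    if method == "DMNC":
        return _dmnc(graph)
    if method == "MCC":
        return _mcc(graph)
    if method == "Bottleneck":
        return _bottleneck(graph)
    if method == "EPC":
        return _epc(graph, seed=seed, n_reps=n_reps)
    raise ValueError(f"unknown centrality method {method!r}")


def centrality_table(
    graph: nx.Graph,
    methods: tuple[str, ...] = METHODS,
    seed: int | None = 0,
    n_reps: int = 1000,
) -> pd.DataFrame:
    """Genes x methods score table."""
    cols = {m: centrality(graph, m, seed=seed, n_reps=n_reps) for m in methods}
    return pd.DataFrame(cols).reindex(sorted(graph.nodes()))


def consensus_hubs(
    table: pd.DataFrame,
    k: int = 50,
    min_methods: int = 6,
) -> tuple[pd.Series, set[str]]:
    """Count, per gene, the methods whose top-k list contains it; select
    genes counted by at least ``min_methods`` methods.

    Top-k ties are broken by gene-id lexicographic order; if the graph has
    fewer than k nodes every node is in every list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 1 <= min_methods <= len(table.columns):
        raise ValueError("min_methods out of range")
    counts = pd.Series(0, index=table.index, dtype=int)
    for method in table.columns:
        ranked = table[method].sort_index().sort_values(ascending=False, kind="stable")
        top = ranked.head(k).index
        counts.loc[top] += 1
    selected = set(counts[counts >= min_methods].index)
    return counts.sort_values(ascending=False), selected


def spearman_biomarker_filter(
    ccl_expr: pd.DataFrame,
    measured_auc: pd.Series,
    candidates: set[str] | list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Signed Spearman screen: selected iff rho < 0 and p < alpha."""
    shared = [s for s in ccl_expr.columns if s in measured_auc.index]
    if len(shared) < 5:
        raise ValueError("need at least 5 cell lines with expression and AUC")
    y = measured_auc.loc[shared].to_numpy(float)
    rows = []
    for gene in sorted(candidates):
        if gene not in ccl_expr.index:
            warnings.warn(f"gene {gene} missing from expression matrix", stacklevel=2)
            continue
        x = ccl_expr.loc[gene, shared].to_numpy(float)
        rho, p = stats.spearmanr(x, y)
        rows.append((gene, rho, p, bool(rho < 0 and p < alpha)))
    return pd.DataFrame(rows, columns=["gene", "rho", "p_value", "selected"])


def stratum_response_test(
    imputed_drug: pd.Series,
    strata: pd.Series,
    group_label: str = "AR_low_Gly_high",
) -> dict:
    """Welch's unequal-variance t-test between the labeled stratum and the rest.

    Returns t, Welch-Satterthwaite df, two-sided p and the group means.
    """
    shared = strata.index.intersection(imputed_drug.index)
    labels = strata.loc[shared]
    g1 = imputed_drug.loc[shared][labels == group_label].to_numpy(float)
    g2 = imputed_drug.loc[shared][labels != group_label].to_numpy(float)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each stratum needs at least 2 samples")
    n1, n2 = len(g1), len(g2)
    v1, v2 = g1.var(ddof=1), g2.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    if se2 == 0:
        se2 = 1e-24  # variance floor for degenerate inputs
        df = n1 + n2 - 2
    else:
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    t = (g1.mean() - g2.mean()) / math.sqrt(se2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return {
        "t": t,
        "df": df,
        "p_value": p,
        "mean_group": g1.mean(),
        "mean_other": g2.mean(),
        "n_group": n1,
        "n_other": n2,
    }
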