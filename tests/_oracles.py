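"""Independent oracles used to cross-check the package's implementations.

Each oracle takes a route disjoint from the code it checks: exhaustive
partition enumeration for modularity, scipy's Floyd-Warshall for shortest
paths, the rank-difference closed form for Spearman, and direct Monte
Carlo for the copula rank-transfer identity.
"""

from __future__ import annotations

import numpy as np
import networkx as nx
from scipy.sparse.csgraph import floyd_warshall
from scipy import stats


def set_partitions(items):
    """Yield all partitions of ``items`` (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [[first] + partition[i]] + partition[i + 1:]
        yield [[first]] + partition


def modularity_of_partition(G: nx.Graph, partition) -> float:
    """Direct evaluation of Q = sum_c [e_c/m - (d_c/2m)^2]."""
    m = G.number_of_edges()
    if m == 0:
        return float("nan")
    degrees = dict(G.degree())
    q = 0.0
    for community in partition:
        community = set(community)
        e_c = sum(1 for u, v in G.edges() if u in community and v in community)
        d_c = sum(degrees[v] for v in community)
        q += e_c / m - (d_c / (2 * m)) ** 2
    return q


def brute_force_max_modularity(G: nx.Graph) -> float:
    """Exact maximum Q over every partition (graphs with <= 8 nodes)."""
    nodes = list(G.nodes())
    assert len(nodes) <= 8, "brute force limited to 8 nodes"
    return max(modularity_of_partition(G, p) for p in set_partitions(nodes))


def floyd_warshall_metrics(G: nx.Graph) -> tuple[float, float]:
    """(average path length over reachable pairs, diameter) via scipy."""
    nodes = list(G.nodes())
    adj = nx.to_numpy_array(G, nodelist=nodes, weight=None)
    dist = floyd_warshall(adj, unweighted=True, directed=False)
    iu = np.triu_indices(len(nodes), k=1)
    pair_d = dist[iu]
    finite = pair_d[np.isfinite(pair_d)]
    if finite.size == 0:
        return 0.0, 0.0
    return float(finite.mean()), float(finite.max())


def spearman_closed_form(x, y) -> float:
    """1 - 6 * sum(d^2) / (n (n^2 - 1)); valid for tie-free vectors."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    rx = np.argsort(np.argsort(x)) + 1
    ry = np.argsort(np.argsort(y)) + 1
    d2 = np.sum((rx - ry) ** 2)
    return 1 - 6 * d2 / (n * (n**2 - 1))


def monte_carlo_spearman(rho: float, n: int = 1_000_000, seed: int = 0) -> float:
    """Empirical Spearman of bivariate-normal draws at latent correlation rho."""
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    return float(stats.spearmanr(z1, z2).statistic)


def random_graph(n_max: int, rng: np.random.Generator, p_edge: float | None = None) -> nx.Graph:
    """Random simple graph with 2..n_max nodes, at least one edge."""
    while True:
        n = int(rng.integers(2, n_max + 1))
        p = float(rng.uniform(0.15, 0.9)) if p_edge is None else p_edge
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if G.number_of_edges() > 0:
            return G
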