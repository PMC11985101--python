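"""Network-level topological features of co-occurrence graphs.

All metrics run on the unweighted, unsigned edge skeleton (negative
correlations count as edges); restrict to positive edges first with
:func:`positive_subgraph` for sensitivity analyses. Path statistics are
averaged over reachable pairs only, which keeps them well-defined for the
fragmented, highly modular graphs typical of thresholded co-occurrence
analysis. Community structure uses seeded Louvain on a lexicographically
ordered node set, so repeated runs agree.
"""

from __future__ import annotations

import logging
import random
import warnings
import zlib
from dataclasses import dataclass, field, asdict
from typing import Mapping

import igraph
import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Louvain restarts per call; best-modularity partition wins. Seeds are
#: derived deterministically from the caller's seed.
LOUVAIN_RESTARTS = 5


@dataclass
class TopologySummary:
    """One network's topology row."""

    ecosystem: str
    n_nodes: int
    n_edges: int
    average_degree: float
    density: float
    average_clustering: float
    average_path_length: float
    diameter: float
    modularity_Q: float  # NaN for edgeless graphs
    n_modules: int
    module_assignment: dict = field(default_factory=dict, repr=False)

    def as_row(self) -> dict:
        d = asdict(self)
        d.pop("module_assignment")
        return d


def positive_subgraph(G: nx.Graph) -> nx.Graph:
    """Subgraph of edges with positive correlation sign."""
    H = nx.Graph(**G.graph)
    H.add_nodes_from(G.nodes(data=True))
    H.add_edges_from(
        (u, v, d) for u, v, d in G.edges(data=True) if d.get("sign", "+") == "+"
    )
    return H


def degree_stats(G: nx.Graph) -> tuple[int, int, float, float]:
    """(n_nodes, n_edges, average_degree, density); zeros for empty graphs."""
    n, m = G.number_of_nodes(), G.number_of_edges()
    if n == 0:
        warnings.warn("degree_stats of an empty graph", stacklevel=2)
        return 0, 0, 0.0, 0.0
    avg_deg = 2.0 * m / n
    density = 0.0 if n < 2 else 2.0 * m / (n * (n - 1))
    return n, m, avg_deg, density


def clustering_coefficient(G: nx.Graph) -> float:
    """Mean local clustering coefficient (degree < 2 contributes 0)."""
    if G.number_of_nodes() == 0:
        warnings.warn("clustering of an empty graph", stacklevel=2)
        return 0.0
    return float(nx.average_clustering(G))


def path_metrics(G: nx.Graph) -> tuple[float, float]:
    """(average_path_length, diameter) over reachable pairs.

    BFS all-pairs shortest paths; unordered pairs in different components
    are excluded (their count is logged). Both are 0 for edgeless graphs.
    """
    n = G.number_of_nodes()
    if n == 0 or G.number_of_edges() == 0:
        warnings.warn("path metrics of an edgeless graph are 0", stacklevel=2)
        return 0.0, 0.0
    total, pairs, diameter = 0, 0, 0
    for _, dists in nx.all_pairs_shortest_path_length(G):
        for d in dists.values():
            if d > 0:
                total += d
                pairs += 1
                diameter = max(diameter, d)
    pairs //= 2  # each unordered pair seen from both ends
    total //= 2
    unreachable = n * (n - 1) // 2 - pairs
    if unreachable:
        logger.info("path_metrics: %d unordered pairs in different components excluded", unreachable)
    return (total / pairs if pairs else 0.0), float(diameter)


def modularity(G: nx.Graph, communities) -> float:
    """Newman modularity Q = sum_c [e_c/m - (d_c/2m)^2] of a partition."""
    return float(nx.community.modularity(G, communities))


def louvain_modularity(
    G: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> tuple[float, int, dict]:
    """Best seeded-Louvain partition of the unweighted skeleton.

    Community detection runs igraph's multilevel (Louvain) implementation
    over a small number of deterministic restarts (seeds spawned from
    ``seed``) and keeps the highest-Q partition; singleton communities
    (isolated nodes) count toward ``n_modules``. Returns
    (modularity_Q, n_modules, node -> community id). Q is NaN for graphs
    without edges.
    """
    if G.number_of_edges() == 0:
        warnings.warn("modularity undefined for an edgeless graph", stacklevel=2)
        return float("nan"), G.number_of_nodes(), {v: i for i, v in enumerate(G.nodes())}
    nodes = sorted(G.nodes(), key=str)  # order-stable across runs
    index = {v: i for i, v in enumerate(nodes)}
    g = igraph.Graph(n=len(nodes), edges=[(index[u], index[v]) for u, v in G.edges()])
    restart_seeds = np.random.SeedSequence(seed).generate_state(LOUVAIN_RESTARTS) % (2**31)
    best_q, best_parts = -np.inf, None
    for s in restart_seeds:
        igraph.set_random_number_generator(random.Random(int(s)))
        clusters = g.community_multilevel(resolution=resolution)
        parts = [{nodes[i] for i in cluster} for cluster in clusters]
        q = nx.community.modularity(G, parts, resolution=resolution)
        if q > best_q:
            best_q, best_parts = q, parts
    ordered = sorted((sorted(c, key=str) for c in best_parts), key=lambda c: c[0])
    assignment = {v: i for i, c in enumerate(ordered) for v in c}
    return float(best_q), len(ordered), assignment


def summarize_network(
    G: nx.Graph, ecosystem: str = "", resolution: float = 1.0, seed: int = 0
) -> TopologySummary:
    """All topology metrics of one network as a :class:`TopologySummary`."""
    n, m, avg_deg, density = degree_stats(G)
    if m == 0:
        return TopologySummary(ecosystem, n, 0, 0.0, density, 0.0, 0.0, 0.0,
                               float("nan"), max(n, 0) if n else 0)
    clustering = clustering_coefficient(G)
    apl, diam = path_metrics(G)
    q, k, assignment = louvain_modularity(G, resolution=resolution, seed=seed)
    return TopologySummary(
        ecosystem=ecosystem, n_nodes=n, n_edges=m, average_degree=avg_deg,
        density=density, average_clustering=clustering,
        average_path_length=apl, diameter=diam,
        modularity_Q=q, n_modules=k, module_assignment=assignment,
    )


def summarize_topology(
    networks: Mapping[str, nx.Graph], resolution: float = 1.0, seed: int = 0
) -> pd.DataFrame:
    """One topology row per ecosystem network, as a DataFrame.

    Louvain seeds are derived per ecosystem from ``seed``, so adding or
    reordering ecosystems does not perturb the others' partitions.
    """
    if not networks:
        raise ValueError("no networks to summarise")
    rows = []
    for name in networks:
        name_key = zlib.crc32(str(name).encode())  # stable across processes
        eco_seed = int(np.random.SeedSequence((seed, name_key)).generate_state(1)[0] % 2**31)
        rows.append(summarize_network(networks[name], ecosystem=name,
                                      resolution=resolution, seed=eco_seed).as_row())
    return pd.DataFrame(rows).set_index("ecosystem")


def annotate_modules(G: nx.Graph, assignment: Mapping) -> nx.Graph:
    """Write the community id into each node's ``module`` attribute."""
    for v in G.nodes():
        G.nodes[v]["module"] = int(assignment.get(v, -1))
    return G
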