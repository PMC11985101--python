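"""Spearman correlation matrices and thresholded co-occurrence networks.

A co-occurrence network has one node per ASV and one undirected edge per
significant pairwise rank correlation: |r| above ``r_threshold`` (default
0.6) and two-sided p below ``p_threshold`` (default 0.05). Edges carry the
coefficient, the p-value and the correlation sign; graph metadata records
the thresholds that built it.

p-values use the standard t approximation, t = r * sqrt((n-2)/(1-r^2)) on
n-2 degrees of freedom. For very small sample sizes (n < 10) the t
approximation is anti-conservative in the tails, so an exact permutation
option (full enumeration of all n! orderings) is available.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .tables import AbundanceTable, TaxonomyMap, relative_abundance

logger = logging.getLogger(__name__)

DEFAULT_R_THRESHOLD = 0.6
DEFAULT_P_THRESHOLD = 0.05


class NetworkError(ValueError):
    pass


@dataclass
class CorrelationResult:
    """Pairwise Spearman coefficients and two-sided p-values.

    ``r`` and ``p`` are symmetric DataFrames indexed by ASV id; pairs
    involving a constant ASV (zero rank variance) have undefined r and are
    set to NaN, with the offending ids listed in ``constant_ids``.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n_samples: int
    constant_ids: list[str]

    def __post_init__(self) -> None:
        rv = self.r.to_numpy()
        if np.nanmax(np.abs(rv - rv.T)) > 1e-12:
            raise NetworkError("correlation matrix not symmetric")


@lru_cache(maxsize=4)
def _exact_perm_matrix(n: int) -> np.ndarray:
    if n > 9:
        raise NetworkError(f"exact permutation p-values limited to n <= 9, got n={n}")
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def _exact_permutation_pvalues(ranks: np.ndarray, r_obs: np.ndarray) -> np.ndarray:
    """Exact two-sided permutation p per pair, conditioning on tie patterns.

    Enumerates all n! orderings of one rank vector; the null distribution of
    the rank correlation is computed for each pair's own (possibly tied)
    rank values, so ties are handled exactly.
    """
    p_asvs, n = ranks.shape
    perms = _exact_perm_matrix(n)  # (n!, n)
    centered = ranks - ranks.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    pvals = np.ones((p_asvs, p_asvs))
    for i in range(p_asvs):
        if norms[i] == 0:
            continue
        xi = centered[i]
        for j in range(i + 1, p_asvs):
            if norms[j] == 0:
                continue
            # correlation of xi with every permutation of ranks[j]
            yj = centered[j][perms]  # (n!, n)
            null_r = (yj @ xi) / (norms[i] * norms[j])
            p = np.mean(np.abs(null_r) >= abs(r_obs[i, j]) - 1e-12)
            pvals[i, j] = pvals[j, i] = p
    np.fill_diagonal(pvals, 0.0)
    return pvals


def spearman_matrix(
    table: AbundanceTable,
    p_method: str = "t",
) -> CorrelationResult:
    """All-pairs Spearman correlation of ASVs across samples.

    Ranks use average (fractional) ranks for ties. ``p_method="t"`` gives
    the usual t-approximation p-values; ``"exact"`` enumerates all sample
    permutations (n <= 9 only). ASVs with constant abundance have undefined
    correlations; they are flagged, set to NaN and excluded downstream.
    """
    n = table.n_samples
    if n < 4:
        raise NetworkError(f"need >= 4 samples for meaningful p-values, got {n}")
    if table.n_asvs < 2:
        raise NetworkError("need >= 2 ASVs to correlate")
    values = table.counts.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise NetworkError("non-finite values in abundance table")

    constant = values.std(axis=1) == 0
    constant_ids = list(table.asv_ids[constant])
    if constant_ids:
        warnings.warn(
            f"{len(constant_ids)} constant ASV(s) have undefined correlations "
            "and are excluded from the network",
            stacklevel=2,
        )
    # Spearman = Pearson correlation of average-rank vectors; constant rows
    # give NaN rather than making the whole matrix undefined.
    ranks = stats.rankdata(values, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip(np.corrcoef(ranks), -1.0, 1.0)
        if p_method == "t":
            tstat = r * np.sqrt((n - 2) / (1.0 - r**2))  # +/-inf at |r| = 1
            p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        elif p_method == "exact":
            p = _exact_permutation_pvalues(ranks, r)
        else:
            raise NetworkError(f"unknown p_method {p_method!r}")
    np.fill_diagonal(p, 0.0)
    r[constant, :] = np.nan
    r[:, constant] = np.nan
    p[constant, :] = np.nan
    p[:, constant] = np.nan
    np.fill_diagonal(r, 1.0)
    idx = table.asv_ids
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n_samples=n,
        constant_ids=constant_ids,
    )


def build_network(
    corr: CorrelationResult,
    r_threshold: float = DEFAULT_R_THRESHOLD,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    table: AbundanceTable | None = None,
    taxonomy: TaxonomyMap | None = None,
    keep_isolates: bool = False,
    fdr: bool = False,
    ecosystem: str | None = None,
) -> nx.Graph:
    """Threshold a correlation result into an undirected signed graph.

    An edge is added iff |r| > ``r_threshold`` AND p < ``p_threshold``
    (Benjamini-Hochberg adjusted p when ``fdr=True``). By default only ASVs
    with at least one significant edge become nodes; ``keep_isolates=True``
    retains every ASV. An empty result is returned (with a warning), never
    raised.
    """
    if not 0 < r_threshold < 1:
        raise NetworkError(f"r_threshold must be in (0,1), got {r_threshold}")
    if not 0 < p_threshold < 1:
        raise NetworkError(f"p_threshold must be in (0,1), got {p_threshold}")

    ids = list(corr.r.index)
    r = corr.r.to_numpy()
    p = corr.p.to_numpy().copy()
    iu = np.triu_indices(len(ids), k=1)
    if fdr:
        flat = p[iu]
        finite = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        if finite.any():
            adj[finite] = _benjamini_hochberg(flat[finite])
        p[iu] = adj
        p[(iu[1], iu[0])] = adj

    with np.errstate(invalid="ignore"):
        sig = (np.abs(r) > r_threshold) & (p < p_threshold)
    sig &= np.isfinite(r)

    mean_rel = None
    if table is not None:
        mean_rel = relative_abundance(table).counts.mean(axis=1)

    G = nx.Graph(
        r_threshold=float(r_threshold),
        p_threshold=float(p_threshold),
        fdr=bool(fdr),
        ecosystem=ecosystem or "",
    )

    def node_attrs(asv: str) -> dict:
        attrs = {"asv_id": asv}
        if table is not None:
            attrs["domain"] = str(table.domain.get(asv, "unknown"))
            attrs["mean_rel_abundance"] = float(mean_rel.get(asv, np.nan))
        if taxonomy is not None:
            attrs["phylum"] = taxonomy.rank(asv, "phylum")
        return attrs

    if keep_isolates:
        for asv in ids:
            if asv not in corr.constant_ids:
                G.add_node(asv, **node_attrs(asv))
    for i, j in zip(*np.nonzero(np.triu(sig, k=1))):
        u, v = ids[i], ids[j]
        for node in (u, v):
            if node not in G:
                G.add_node(node, **node_attrs(node))
        G.add_edge(u, v, r=float(r[i, j]), p=float(p[i, j]),
                   sign="+" if r[i, j] > 0 else "-")

    if G.number_of_edges() == 0:
        warnings.warn(
            "no correlation passed the thresholds; returning an "
            f"{'isolate-only' if G.number_of_nodes() else 'empty'} network",
            stacklevel=2,
        )
    logger.info(
        "build_network: %d nodes, %d edges at |r|>%g, p<%g",
        G.number_of_nodes(), G.number_of_edges(), r_threshold, p_threshold,
    )
    return G


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone step-up)."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    adj[order] = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
    return np.minimum(adj, 1.0)


class SpearmanNetworkBuilder(BaseEstimator):
    """Estimator inferring a thresholded co-occurrence network from a table.

    ``fit(X)`` computes the all-pairs Spearman matrix of X (an
    :class:`AbundanceTable` or ASV x sample DataFrame) and thresholds it.
    Fitted attributes: ``correlation_`` (:class:`CorrelationResult`),
    ``network_`` (:class:`networkx.Graph`), ``n_edges_``, ``n_nodes_``.
    """

    def __init__(
        self,
        r_threshold: float = DEFAULT_R_THRESHOLD,
        p_threshold: float = DEFAULT_P_THRESHOLD,
        p_method: str = "t",
        fdr: bool = False,
        keep_isolates: bool = False,
    ):
        self.r_threshold = r_threshold
        self.p_threshold = p_threshold
        self.p_method = p_method
        self.fdr = fdr
        self.keep_isolates = keep_isolates

    def fit(self, X, y=None, taxonomy: TaxonomyMap | None = None, ecosystem: str | None = None):
        table = X if isinstance(X, AbundanceTable) else AbundanceTable(pd.DataFrame(X))
        self.correlation_ = spearman_matrix(table, p_method=self.p_method)
        self.network_ = build_network(
            self.correlation_,
            r_threshold=self.r_threshold,
            p_threshold=self.p_threshold,
            table=table,
            taxonomy=taxonomy,
            keep_isolates=self.keep_isolates,
            fdr=self.fdr,
            ecosystem=ecosystem,
        )
        self.n_nodes_ = self.network_.number_of_nodes()
        self.n_edges_ = self.network_.number_of_edges()
        return self


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_edge_list(G: nx.Graph, path: str | Path) -> None:
    """Edge list CSV: source, target, r, p, sign."""
    rows = [
        {"source": u, "target": v, "r": d["r"], "p": d["p"], "sign": d["sign"]}
        for u, v, d in G.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "r", "p", "sign"]).to_csv(path, index=False)


def write_graph(G: nx.Graph, path: str | Path) -> None:
    """Write GEXF or GraphML (by extension) with all node/edge attributes."""
    path = Path(path)
    H = G.copy()
    for _, d in H.nodes(data=True):  # NaN attributes break both writers
        for k, v in list(d.items()):
            if isinstance(v, float) and not np.isfinite(v):
                d[k] = 0.0
    if path.suffix == ".gexf":
        nx.write_gexf(H, path)
    elif path.suffix == ".graphml":
        nx.write_graphml(H, path)
    else:
        raise NetworkError(f"unsupported graph format {path.suffix!r} (use .gexf or .graphml)")
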