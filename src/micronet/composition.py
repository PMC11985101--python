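"""Taxonomic composition of network nodes.

Summarises which phyla the nodes of each co-occurrence network belong to,
either as a plain node-count fraction or weighted by each node's mean
relative abundance. Fractions sum to one per network.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Literal, Mapping

import networkx as nx
import pandas as pd

from .tables import TaxonomyMap


def network_phylum_composition(
    G: nx.Graph,
    taxonomy: TaxonomyMap | None = None,
    weight: Literal["node-count", "abundance"] = "node-count",
) -> pd.Series:
    """Fraction of network nodes per phylum.

    Nodes missing from the taxonomy fall into an explicit "unclassified"
    bucket. ``weight="abundance"`` weights each node by its
    ``mean_rel_abundance`` attribute instead of counting it once; the two
    modes coincide when all abundances are equal.
    """
    if weight not in ("node-count", "abundance"):
        raise ValueError(f"unknown weighting {weight!r}")
    if G.number_of_nodes() == 0:
        warnings.warn("empty network has no composition", stacklevel=2)
        return pd.Series(dtype=float, name="fraction")

    weights: dict[str, float] = {}
    for node, data in G.nodes(data=True):
        phylum = data.get("phylum")
        if phylum is None:
            phylum = taxonomy.rank(node, "phylum") if taxonomy is not None else "unclassified"
        w = 1.0
        if weight == "abundance":
            w = float(data.get("mean_rel_abundance", 0.0))
        weights[phylum] = weights.get(phylum, 0.0) + w
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("abundance weighting requires positive mean_rel_abundance attributes")
    frac = pd.Series(weights, name="fraction") / total
    frac.index.name = "phylum"
    return frac.sort_values(ascending=False)


def composition_table(
    networks: Mapping[str, nx.Graph],
    taxonomy: TaxonomyMap | None = None,
    weight: Literal["node-count", "abundance"] = "node-count",
) -> pd.DataFrame:
    """Long-format (ecosystem, phylum, fraction, weighting) table."""
    rows = []
    for eco, G in networks.items():
        if G.number_of_nodes() == 0:
            continue
        frac = network_phylum_composition(G, taxonomy=taxonomy, weight=weight)
        for phylum, f in frac.items():
            rows.append({"ecosystem": eco, "phylum": phylum, "fraction": f, "weighting": weight})
    return pd.DataFrame(rows, columns=["ecosystem", "phylum", "fraction", "weighting"])


def write_composition(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
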